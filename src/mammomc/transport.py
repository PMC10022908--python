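"""Analog Monte Carlo photon transport in the phantom assembly.

Physics model: photoelectric absorption (full local deposition, no
fluorescence — the K shells of H/C/N/O are below the 1 keV cutoff),
incoherent scattering with free-electron Klein-Nishina kinematics (the
electron energy E - E' deposits at the collision site, the kerma
approximation), and coherent (Rayleigh) scattering from tabulated atomic
form factors (redirection only).  Transport is analog: every photon carries
weight one, there is no variance reduction.  Histories are advanced in
vectorized batches; a history ends by photoelectric absorption, by falling
below the energy cutoff (the residual deposits locally) or by escaping the
geometry.

Energy is conserved exactly by construction: for every history the source
energy equals the sum of its deposits plus its escaped energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import PhantomAssembly, WORLD_ID, BOUNDARY_PUSH, locate
from .materials import Material, XsecLibrary, default_library
from .tallies import TallyResult, finalize

__all__ = [
    "PhotonState", "SimulationConfig",
    "emit_photon", "emit_photons", "sample_free_path",
    "sample_compton", "sample_rayleigh",
    "transport_history", "run_simulation", "HistoryLedger",
]

ELECTRON_REST_KEV = 510.99895
HC_KEV_A = 12.398419843


@dataclass
class PhotonState:
    """One photon in flight (analog mode: weight is always 1)."""

    position: np.ndarray
    direction: np.ndarray
    energy: float        # keV
    weight: float = 1.0
    region: int = WORLD_ID
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector")
        if self.energy <= 0:
            raise ValueError("energy must be positive")


@dataclass
class SimulationConfig:
    """Parameters of one Monte Carlo run.

    ``mode='absorber'`` is a test support mode in which every interaction
    uses the photoelectric coefficient only and absorbs the photon — the
    geometry then obeys the closed-form layered-absorber formula.
    """

    assembly: PhantomAssembly
    source_energy_keV: float
    nps: int
    seed: int
    cutoff_keV: float = 1.0
    coherent_enabled: bool = True
    incoherent_sfunc: bool = False
    batches: int = 10
    mode: str = "analog"              # analog | absorber
    beam: str = "cone"                # cone | pencil
    chunk_size: int = 200_000
    max_steps: int = 1_000_000
    library: XsecLibrary | None = None

    def __post_init__(self):
        if self.nps < self.batches:
            raise ValueError("nps must be at least the number of batches")
        if self.cutoff_keV >= self.source_energy_keV:
            raise ValueError("cutoff must be below the source energy")
        if self.mode not in ("analog", "absorber"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.beam not in ("cone", "pencil"):
            raise ValueError(f"unknown beam {self.beam!r}")


# -- elementary samplers ---------------------------------------------------

def sample_free_path(mu, rng):
    """Exponential free path d = -ln(U)/mu for linear attenuation mu (1/cm)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("attenuation coefficient must be positive")
    u = rng.random(mu.shape) if mu.ndim else rng.random()
    return -np.log1p(-u) / mu


def _kn_unnormalized(energy_keV, cos_theta):
    alpha = np.asarray(energy_keV, dtype=float) / ELECTRON_REST_KEV
    k = 1.0 / (1.0 + alpha * (1.0 - cos_theta))
    return k * k * (k + 1.0 / k - 1.0 + cos_theta * cos_theta)


def _sample_kn_cos(energy_keV: np.ndarray, rng) -> np.ndarray:
    """Klein-Nishina cos(theta) by rejection under the constant envelope 2.

    The free-electron Klein-Nishina density (in cos theta, unnormalized as
    written in :func:`_kn_unnormalized`) is bounded by its forward value 2
    for every energy, so uniform proposals on [-1, 1] accepted with ratio
    f/2 sample it exactly; acceptance is ~2/3 at mammographic energies.
    """
    e = np.asarray(energy_keV, dtype=float)
    out = np.empty(e.shape)
    todo = np.arange(e.size)
    while todo.size:
        prop = rng.random(todo.size) * 2.0 - 1.0
        h = rng.random(todo.size)
        acc = 2.0 * h <= _kn_unnormalized(e[todo], prop)
        out[todo[acc]] = prop[acc]
        todo = todo[~acc]
    return out


def sample_compton(energy_keV, rng):
    """Sample a Compton event: returns (scattered_energy_keV, cos_theta).

    cos(theta) follows the free-electron Klein-Nishina distribution and the
    scattered energy the Compton relation E' = E / (1 + alpha (1 - cos)),
    alpha = E / 511 keV.  The difference E - E' is the electron energy
    deposited locally under the kerma approximation.
    """
    scalar = np.ndim(energy_keV) == 0
    e = np.atleast_1d(np.asarray(energy_keV, dtype=float))
    mu = _sample_kn_cos(e, rng)
    eprime = e / (1.0 + e / ELECTRON_REST_KEV * (1.0 - mu))
    if scalar:
        return float(eprime[0]), float(mu[0])
    return eprime, mu


def sample_rayleigh(energy_keV, material: Material, rng,
                    library: XsecLibrary | None = None):
    """Sample the Rayleigh scattering angle cos(theta) in ``material``.

    The scattering atom is chosen with probability proportional to
    ``w_i (mu_coh/rho)_i(E)``; the angle then follows the Thomson
    distribution modulated by that atom's squared form factor, via
    rejection sampling.  The photon energy is unchanged (elastic) and no
    energy is deposited.
    """
    library = library or default_library()
    scalar = np.ndim(energy_keV) == 0
    e = np.atleast_1d(np.asarray(energy_keV, dtype=float))
    syms, probs = library.element_coherent_weights(material, float(e[0]))
    # per-photon element pick (weights evaluated at each photon's energy)
    if e.size > 1:
        wts = np.stack([
            np.asarray([material.fractions[s]] * e.size) *
            library.tables[s].interp(e, "coh") for s in syms
        ])
        wts /= wts.sum(axis=0)
    else:
        wts = np.asarray(probs)[:, None]
    pick = (rng.random(e.size)[None, :] > np.cumsum(wts, axis=0)).sum(axis=0)
    pick = np.minimum(pick, len(syms) - 1)

    lam = HC_KEV_A / e
    inv_2lam2 = 1.0 / (2.0 * lam * lam)
    out = np.empty(e.size)
    for k, s in enumerate(syms):
        sel = np.flatnonzero(pick == k)
        if not sel.size:
            continue
        x2g, cum = library.form_factors[s].x2_cumulative
        # momentum transfer is capped at x_max = 1/lambda (backscatter)
        area = np.interp(2.0 * inv_2lam2[sel], x2g, cum)
        todo = np.arange(sel.size)
        vals = np.empty(sel.size)
        while todo.size:
            u = rng.random(todo.size) * area[todo]
            x2 = np.interp(u, cum, x2g)
            mu = 1.0 - x2 / inv_2lam2[sel[todo]]
            acc = rng.random(todo.size) * 2.0 <= 1.0 + mu * mu
            vals[todo[acc]] = mu[acc]
            todo = todo[~acc]
        out[sel] = vals
    return float(out[0]) if scalar else out


# -- source ----------------------------------------------------------------

def emit_photons(assembly: PhantomAssembly, energy_keV: float, n: int, rng,
                 beam: str = "cone"):
    """Emit ``n`` source photons: positions, unit directions, energies.

    Cone beam: directions are uniform in solid angle within the circular
    cone circumscribing the rectangular entrance field as seen from the
    point source, rejected onto the field rectangle, so the accepted
    directions are uniform in solid angle over the collimation pyramid and
    every photon crosses the entrance field.  Pencil beam: all photons
    travel straight down from the source.
    """
    src = np.asarray(assembly.source_position, dtype=float)
    pos = np.tile(src, (n, 1))
    energies = np.full(n, float(energy_keV))
    if beam == "pencil":
        dirs = np.tile(np.array([0.0, 0.0, -1.0]), (n, 1))
        return pos, dirs, energies

    xlo, xhi, ylo, yhi = assembly.field
    dz = assembly.field_z - src[2]          # negative: field below source
    corners = np.array([[x, y] for x in (xlo, xhi) for y in (ylo, yhi)])
    rel = corners - src[:2]
    cos_max = (-dz) / np.sqrt((rel ** 2).sum(axis=1) + dz * dz)
    cos_min_allowed = cos_max.min()

    dirs = np.empty((n, 3))
    todo = np.arange(n)
    while todo.size:
        c = cos_min_allowed + (1.0 - cos_min_allowed) * rng.random(todo.size)
        phi = 2.0 * np.pi * rng.random(todo.size)
        s = np.sqrt(1.0 - c * c)
        d = np.column_stack([s * np.cos(phi), s * np.sin(phi), -c])
        t = dz / d[:, 2]
        hx = src[0] + t * d[:, 0]
        hy = src[1] + t * d[:, 1]
        ok = (hx >= xlo) & (hx <= xhi) & (hy >= ylo) & (hy <= yhi)
        dirs[todo[ok]] = d[ok]
        todo = todo[~ok]
    return pos, dirs, energies


def emit_photon(assembly: PhantomAssembly, energy_keV: float, rng,
                beam: str = "cone") -> PhotonState:
    """Emit a single source photon as a :class:`PhotonState`."""
    pos, dirs, e = emit_photons(assembly, energy_keV, 1, rng, beam)
    return PhotonState(pos[0], dirs[0], float(e[0]),
                       region=locate(assembly, pos[0]))


# -- material physics cache -------------------------------------------------

class _Physics:
    """Per-region material data laid out for vectorized evaluation."""

    def __init__(self, assembly: PhantomAssembly, library: XsecLibrary,
                 coherent_enabled: bool, mode: str):
        self.coherent_enabled = coherent_enabled
        self.mode = mode
        mats: list[Material] = []
        mat_index: dict[str, int] = {}
        max_id = max((r.id for r in assembly.regions), default=0)
        self.region_slot = np.full(max_id + 2, -1, dtype=np.int32)
        self.tally_row = np.full(max_id + 2, -1, dtype=np.int32)
        for row, r in enumerate(assembly.regions):
            if r.material.name not in mat_index:
                mat_index[r.material.name] = len(mats)
                mats.append(r.material)
            self.region_slot[r.id] = mat_index[r.material.name]
            self.tally_row[r.id] = row
        self.materials = mats
        # per material, per channel: element (loge grid, log mu) plus weights
        self._interp = []
        for m in mats:
            per_channel = {}
            for ch in ("pe", "inc", "coh"):
                per_channel[ch] = [
                    (w, library.tables[s]._loge, library.tables[s]._logmu[ch])
                    for s, w in m.fractions.items() if w > 0
                ]
            self._interp.append(per_channel)
        self.density = np.array([m.density for m in mats])

    def linear_mu(self, slot: int, energy_keV: np.ndarray):
        """(mu_pe, mu_inc, mu_coh) in 1/cm for material slot at energies."""
        loge = np.log(energy_keV)
        rho = self.density[slot]
        out = []
        for ch in ("pe", "inc", "coh"):
            acc = 0.0
            for w, lg, lm in self._interp[slot][ch]:
                acc = acc + w * np.exp(np.interp(loge, lg, lm))
            out.append(rho * acc)
        return out

    def total_mu(self, slot: int, energy_keV: np.ndarray) -> np.ndarray:
        pe, inc, coh = self.linear_mu(slot, energy_keV)
        if self.mode == "absorber":
            return pe
        if not self.coherent_enabled:
            return pe + inc
        return pe + inc + coh


def _rotate(directions: np.ndarray, cos_t: np.ndarray, phi: np.ndarray):
    """Rotate unit vectors by polar angle (cos_t) and azimuth phi."""
    w = directions
    # stable perpendicular basis (helper = z-hat where |w_z| < 0.9, else x-hat)
    small_z = np.abs(w[:, 2]) < 0.9
    u = np.empty_like(w)
    # z-hat x w = (-wy, wx, 0); x-hat x w = (0, -wz, wy)
    u[small_z, 0] = -w[small_z, 1]
    u[small_z, 1] = w[small_z, 0]
    u[small_z, 2] = 0.0
    u[~small_z, 0] = 0.0
    u[~small_z, 1] = -w[~small_z, 2]
    u[~small_z, 2] = w[~small_z, 1]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(w, u)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t * cos_t))
    out = (
        cos_t[:, None] * w
        + sin_t[:, None] * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
    )
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


# -- vectorized transport kernel -------------------------------------------

def _transport_chunk(config: SimulationConfig, physics: _Physics,
                     pos, dirn, energy, rng, deposits: np.ndarray):
    """Transport a chunk of photons to completion.

    ``deposits`` (one row per assembly region, MeV... accumulated in keV by
    the caller's convention: values here are keV) is updated in place.
    Returns (escaped_energy_keV, n_escaped_uncollided, n_escaped).
    """
    assembly = config.assembly
    library = config.library or default_library()
    n = pos.shape[0]
    region = assembly.locate_many(pos)
    ncoll = np.zeros(n, dtype=np.int32)
    escaped = 0.0
    n_unc = 0
    n_esc = 0
    steps = 0
    while pos.shape[0]:
        steps += 1
        if steps > config.max_steps:
            raise RuntimeError("transport did not terminate: geometry bug?")
        t_surf = assembly.surface_distances(pos, dirn)
        slot = physics.region_slot[region]
        mu = np.zeros(pos.shape[0])
        mu_pe = np.zeros(pos.shape[0])
        mu_inc = np.zeros(pos.shape[0])
        for s in np.unique(slot):
            if s < 0:
                continue
            m = slot == s
            pe, inc, coh = physics.linear_mu(s, energy[m])
            mu_pe[m] = pe
            mu_inc[m] = inc
            if config.mode == "absorber":
                mu[m] = pe
            elif physics.coherent_enabled:
                mu[m] = pe + inc + coh
            else:
                mu[m] = pe + inc
        d_coll = np.full(pos.shape[0], np.inf)
        has_mat = mu > 0
        if has_mat.any():
            d_coll[has_mat] = -np.log1p(-rng.random(int(has_mat.sum()))) / mu[has_mat]
        collide = d_coll < t_surf
        esc = ~collide & ~np.isfinite(t_surf)
        cross = ~collide & ~esc

        if esc.any():
            escaped += float(energy[esc].sum())
            n_esc += int(esc.sum())
            n_unc += int((esc & (ncoll == 0)).sum())

        step = np.where(collide, d_coll, t_surf + BOUNDARY_PUSH)
        moved = collide | cross
        pos[moved] += step[moved, None] * dirn[moved]
        if cross.any():
            region[cross] = assembly.locate_many(pos[cross])

        kill = esc.copy()
        if collide.any():
            ci = np.flatnonzero(collide)
            ncoll[ci] += 1
            rows = physics.tally_row[region[ci]]
            e_c = energy[ci]
            slot_c = physics.region_slot[region[ci]]
            if config.mode == "absorber":
                np.add.at(deposits, rows, e_c)
                kill[ci] = True
            else:
                # channel selection (attenuation already evaluated above)
                p_pe = mu_pe[ci] / mu[ci]
                p_inc = mu_inc[ci] / mu[ci]
                u = rng.random(ci.size)
                is_pe = u < p_pe
                is_inc = ~is_pe & (u < p_pe + p_inc)
                is_coh = ~is_pe & ~is_inc

                if is_pe.any():
                    idx = ci[is_pe]
                    np.add.at(deposits, rows[is_pe], energy[idx])
                    kill[idx] = True
                if is_inc.any():
                    idx = ci[is_inc]
                    eprime, cos_t = sample_compton(energy[idx], rng)
                    if config.incoherent_sfunc:
                        eprime, cos_t = _sfunc_correct(
                            config, physics, library, rng,
                            energy[idx], eprime, cos_t, slot_c[is_inc])
                    np.add.at(deposits, rows[is_inc], energy[idx] - eprime)
                    below = eprime <= config.cutoff_keV
                    if below.any():
                        np.add.at(deposits, rows[is_inc][below], eprime[below])
                        kill[idx[below]] = True
                    live = ~below
                    energy[idx] = np.where(below, energy[idx], eprime)
                    if live.any():
                        phi = 2.0 * np.pi * rng.random(int(live.sum()))
                        dirn[idx[live]] = _rotate(
                            dirn[idx[live]], cos_t[live], phi)
                if is_coh.any():
                    idx = ci[is_coh]
                    cos_t = _sample_rayleigh_slots(
                        physics, library, rng, energy[idx], slot_c[is_coh])
                    phi = 2.0 * np.pi * rng.random(idx.size)
                    dirn[idx] = _rotate(dirn[idx], cos_t, phi)

        keep = ~kill
        pos = pos[keep]
        dirn = dirn[keep]
        energy = energy[keep]
        region = region[keep]
        ncoll = ncoll[keep]
    return escaped, n_unc, n_esc


def _sample_rayleigh_slots(physics, library, rng, energies, slots):
    out = np.empty(energies.size)
    for s in np.unique(slots):
        m = slots == s
        out[m] = sample_rayleigh(energies[m], physics.materials[s], rng, library)
    return out


def _sfunc_correct(config, physics, library, rng, e0, eprime, cos_t, slots):
    """Optional incoherent-scattering-function rejection on KN samples."""
    todo = np.arange(e0.size)
    lam = HC_KEV_A / e0
    while todo.size:
        x = np.sqrt((1.0 - cos_t[todo]) / 2.0) / lam[todo]
        ratio = np.empty(todo.size)
        for s in np.unique(slots[todo]):
            m = slots[todo] == s
            mat = physics.materials[s]
            num = 0.0
            den = 0.0
            for sym, w in mat.fractions.items():
                if w <= 0:
                    continue
                ff = library.form_factors[sym]
                num = num + w / ff.Z * ff.s_incoherent(x[m])
                den = den + w
            ratio[m] = num / den
        acc = rng.random(todo.size) <= ratio
        rej = todo[~acc]
        if rej.size:
            ep, ct = sample_compton(e0[rej], rng)
            eprime[rej] = ep
            cos_t[rej] = ct
        todo = rej
    return eprime, cos_t


# -- public drivers ---------------------------------------------------------

@dataclass
class HistoryLedger:
    """Per-history energy bookkeeping returned by :func:`transport_history`."""

    deposits_keV: np.ndarray      # one entry per assembly region
    escaped_keV: float

    @property
    def total_keV(self) -> float:
        return float(self.deposits_keV.sum() + self.escaped_keV)


def transport_history(config: SimulationConfig, state: PhotonState,
                      tally: np.ndarray | None = None) -> HistoryLedger:
    """Transport a single photon history and tally its energy deposits.

    ``tally`` (keV per assembly region, in region order) is updated in
    place when given.  Returns the history's ledger; the source energy
    equals deposits plus escaped energy exactly.
    """
    if not state.alive:
        raise ValueError("photon is not alive")
    rng = np.random.default_rng(config.seed)
    deposits = np.zeros(len(config.assembly.regions))
    physics = _Physics(config.assembly, config.library or default_library(),
                       config.coherent_enabled, config.mode)
    escaped, _, _ = _transport_chunk(
        config, physics,
        state.position[None, :].copy(), state.direction[None, :].copy(),
        np.array([state.energy]), rng, deposits)
    if tally is not None:
        tally += deposits
    state.alive = False
    return HistoryLedger(deposits, escaped)


def run_simulation(config: SimulationConfig) -> TallyResult:
    """Run ``nps`` histories in batches and return the finalized tally.

    The batch structure provides the batch-means uncertainty estimate; the
    run is bit-reproducible for a fixed (config, seed).
    """
    assembly = config.assembly
    library = config.library or default_library()
    physics = _Physics(assembly, library, config.coherent_enabled, config.mode)
    rng = np.random.default_rng(config.seed)
    nreg = len(assembly.regions)
    base, extra = divmod(config.nps, config.batches)
    batch_sizes = [base + (1 if b < extra else 0) for b in range(config.batches)]
    batch_deposits = np.zeros((config.batches, nreg))
    batch_escaped = np.zeros(config.batches)
    batch_unc = np.zeros(config.batches, dtype=np.int64)
    batch_esc_n = np.zeros(config.batches, dtype=np.int64)
    for b, nb in enumerate(batch_sizes):
        done = 0
        while done < nb:
            m = min(config.chunk_size, nb - done)
            pos, dirn, energy = emit_photons(
                assembly, config.source_energy_keV, m, rng, config.beam)
            esc, unc, nesc = _transport_chunk(
                config, physics, pos, dirn, energy, rng, batch_deposits[b])
            batch_escaped[b] += esc
            batch_unc[b] += unc
            batch_esc_n[b] += nesc
            done += m
    return finalize(
        batch_deposits_keV=batch_deposits,
        batch_sizes=np.array(batch_sizes),
        assembly=assembly,
        seed=config.seed,
        source_energy_keV=config.source_energy_keV,
        batch_escaped_keV=batch_escaped,
        n_uncollided_escaped=int(batch_unc.sum()),
        n_escaped=int(batch_esc_n.sum()),
    )
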