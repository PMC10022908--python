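"""Element photon cross-section tables and material mixtures.

The transport engine works with partial mass attenuation coefficients
(photoelectric, incoherent/Compton, coherent/Rayleigh, in cm^2/g) for the
four tissue elements H, C, N, O on a log-spaced 1-100 keV grid.  The element
tables are shipped as plain-text CSV fixtures under ``mammomc/data`` and are
combined into materials with the standard mixture rule

    (mu/rho)_mix(E) = sum_i w_i (mu/rho)_i(E),

with ``w_i`` the element mass fractions.  Interpolation is log-log linear
per element; the total coefficient is always the exact sum of the three
partial channels.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ElementXsecTable",
    "FormFactorTable",
    "Material",
    "XsecLibrary",
    "builtin_materials",
    "default_library",
    "mass_attenuation",
    "linear_attenuation",
    "channel_probabilities",
    "CHANNELS",
]

CHANNELS = ("pe", "inc", "coh", "total")

#: standard atomic weights (g/mol) for the supported elements
ATOMIC_WEIGHTS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}
ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8}


@dataclass(frozen=True)
class ElementXsecTable:
    """Partial mass attenuation coefficients of one element on an energy grid.

    Parameters
    ----------
    symbol : str
        Element symbol (e.g. ``"O"``).
    Z : int
        Atomic number.
    energy_grid : ndarray
        Photon energies in keV, strictly increasing, spanning at least
        1-100 keV.
    mu_pe, mu_inc, mu_coh : ndarray
        Photoelectric, incoherent and coherent mass attenuation
        coefficients (cm^2/g) aligned with ``energy_grid``.
    """

    symbol: str
    Z: int
    energy_grid: np.ndarray
    mu_pe: np.ndarray
    mu_inc: np.ndarray
    mu_coh: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_grid, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError(f"{self.symbol}: energy grid must be 1-D with >=2 points")
        if not np.all(np.diff(e) > 0):
            raise ValueError(f"{self.symbol}: energy grid must be strictly increasing")
        if e[0] > 1.0 or e[-1] < 100.0:
            raise ValueError(f"{self.symbol}: grid must span at least 1-100 keV")
        for name in ("mu_pe", "mu_inc", "mu_coh"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != e.shape:
                raise ValueError(f"{self.symbol}: {name} not aligned with grid")
            if not np.all(arr > 0):
                raise ValueError(f"{self.symbol}: {name} must be positive everywhere")
        # K-edges of H/C/N/O are all below 1 keV, so the photoelectric
        # coefficient must fall monotonically over the whole grid.
        if not np.all(np.diff(self.mu_pe) < 0):
            raise ValueError(f"{self.symbol}: photoelectric channel not monotone decreasing")
        object.__setattr__(self, "energy_grid", e)
        object.__setattr__(self, "_loge", np.log(e))
        object.__setattr__(self, "_logmu", {
            "pe": np.log(self.mu_pe),
            "inc": np.log(self.mu_inc),
            "coh": np.log(self.mu_coh),
        })

    def interp(self, energy_keV, channel: str):
        """Log-log interpolated partial coefficient (cm^2/g) at ``energy_keV``.

        ``channel`` is one of ``pe``, ``inc``, ``coh`` or ``total``.
        Energies outside the grid span raise ``ValueError``.
        """
        e = np.asarray(energy_keV, dtype=float)
        if np.any(e < self.energy_grid[0]) or np.any(e > self.energy_grid[-1]):
            raise ValueError(
                f"energy outside table span "
                f"[{self.energy_grid[0]}, {self.energy_grid[-1]}] keV"
            )
        loge = np.log(e)
        if channel == "total":
            out = sum(
                np.exp(np.interp(loge, self._loge, self._logmu[c]))
                for c in ("pe", "inc", "coh")
            )
        elif channel in self._logmu:
            out = np.exp(np.interp(loge, self._loge, self._logmu[channel]))
        else:
            raise ValueError(f"unknown channel {channel!r}")
        return out if np.ndim(energy_keV) else float(out)


@dataclass(frozen=True)
class FormFactorTable:
    """Atomic form factor F(x) of one element on a momentum-transfer grid.

    ``x = sin(theta/2) / lambda`` in inverse Angstrom; ``F(0) = Z``.
    Used by the coherent (Rayleigh) angle sampler and by the optional
    incoherent scattering-function correction S(x) ~ Z (1 - (F/Z)^2).
    """

    symbol: str
    Z: int
    x_grid: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_grid, dtype=float)
        f = np.asarray(self.F, dtype=float)
        if not np.all(np.diff(x) > 0) or x[0] != 0.0:
            raise ValueError(f"{self.symbol}: x grid must start at 0 and increase")
        if abs(f[0] - self.Z) > 1e-3 * self.Z:
            raise ValueError(f"{self.symbol}: F(0) must equal Z")
        object.__setattr__(self, "x_grid", x)
        object.__setattr__(self, "F", f)

    def eval(self, x):
        return np.interp(x, self.x_grid, self.F)

    @property
    def x2_cumulative(self):
        """(x^2 grid, cumulative integral of F^2 over x^2) for angle sampling."""
        cached = getattr(self, "_x2cum", None)
        if cached is None:
            x2 = self.x_grid**2
            f2 = self.F**2
            cum = np.concatenate([[0.0], np.cumsum(
                0.5 * (f2[1:] + f2[:-1]) * np.diff(x2))])
            cached = (x2, cum)
            object.__setattr__(self, "_x2cum", cached)
        return cached

    def s_incoherent(self, x):
        """Approximate incoherent scattering function S(x)."""
        f = self.eval(x) / self.Z
        return self.Z * (1.0 - f * f)


@dataclass(frozen=True)
class Material:
    """A named elemental mixture with a mass density.

    ``fractions`` maps element symbols to mass fractions which must sum to
    one within 1e-6.  ``gf_percent`` optionally labels breast-tissue
    mixtures with their glandular fraction.
    """

    name: str
    fractions: Mapping[str, float]
    density: float  # g/cm^3
    gf_percent: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        total = math.fsum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"{self.name}: mass fractions sum to {total:.8f}, expected 1"
            )
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError(f"{self.name}: negative mass fraction")
        object.__setattr__(self, "fractions", dict(self.fractions))

    @classmethod
    def from_percent(
        cls, name: str, percents: Mapping[str, float], density: float,
        gf_percent: float | None = None,
    ) -> "Material":
        """Build from weight percentages, renormalizing to an exact unit sum.

        Published tissue tables round their rows to 99.8-100.1%; transport
        needs exact normalization, so the rounded weights are rescaled.
        """
        total = math.fsum(percents.values())
        fractions = {k: v / total for k, v in percents.items()}
        return cls(name, fractions, density, gf_percent)


def builtin_materials() -> dict[str, Material]:
    """The packaged materials.

    ``GF25``/``GF50``/``GF75``/``Skin`` carry the published three-layer
    breast compositions and densities (weight percent H/C/N/O, renormalized);
    ``PMMA`` is the compression-plate surrogate; ``BodyTissue`` is a
    four-element soft-tissue approximation for the chest block; ``Adipose``
    and ``Glandular`` (Hammerstein-type compositions) support the
    homogeneous validation phantom, pre-mixed 80/20 as ``Adipose80Glandular20``.
    """
    m = {
        "GF25": Material.from_percent(
            "GF25", {"H": 11.0, "C": 51.0, "N": 2.1, "O": 35.7}, 0.955, gf_percent=25.0),
        "GF50": Material.from_percent(
            "GF50", {"H": 10.7, "C": 40.1, "N": 2.5, "O": 46.4}, 0.982, gf_percent=50.0),
        "GF75": Material.from_percent(
            "GF75", {"H": 10.5, "C": 29.3, "N": 2.9, "O": 57.0}, 1.010, gf_percent=75.0),
        "Skin": Material.from_percent(
            "Skin", {"H": 9.8, "C": 17.8, "N": 5.0, "O": 66.7}, 1.090),
        "PMMA": Material.from_percent(
            "PMMA", {"H": 8.05, "C": 59.98, "O": 31.96}, 1.19),
        "BodyTissue": Material.from_percent(
            "BodyTissue", {"H": 10.1, "C": 11.1, "N": 2.6, "O": 76.2}, 1.00),
        "Adipose": Material.from_percent(
            "Adipose", {"H": 11.2, "C": 61.9, "N": 1.7, "O": 25.1}, 0.93),
        "Glandular": Material.from_percent(
            "Glandular", {"H": 10.2, "C": 18.4, "N": 3.2, "O": 67.7}, 1.04),
    }
    # 80% adipose / 20% glandular by mass; density from mass-weighted volumes
    wa, wg = 0.8, 0.2
    fr = {
        el: wa * m["Adipose"].fractions.get(el, 0.0) + wg * m["Glandular"].fractions.get(el, 0.0)
        for el in ("H", "C", "N", "O")
    }
    rho = 1.0 / (wa / m["Adipose"].density + wg / m["Glandular"].density)
    m["Adipose80Glandular20"] = Material("Adipose80Glandular20", fr, rho, gf_percent=20.0)
    return m


class XsecLibrary:
    """Loads the packaged element tables and evaluates mixture coefficients."""

    def __init__(self, tables: Mapping[str, ElementXsecTable] | None = None,
                 form_factors: Mapping[str, FormFactorTable] | None = None):
        self.tables = dict(tables) if tables is not None else _load_packaged_xsec()
        self.form_factors = (
            dict(form_factors) if form_factors is not None else _load_packaged_ff()
        )

    # -- mixture rule -----------------------------------------------------

    def mass_attenuation(self, material: Material, energy_keV, channel: str = "total"):
        """Mixture mass attenuation coefficient (cm^2/g)."""
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        out = 0.0
        for sym, w in material.fractions.items():
            if w == 0.0:
                continue
            out = out + w * self.tables[sym].interp(energy_keV, channel)
        return out

    def linear_attenuation(self, material: Material, energy_keV):
        """Linear attenuation coefficient (1/cm): density x total mu/rho."""
        return material.density * self.mass_attenuation(material, energy_keV, "total")

    def channel_probabilities(self, material: Material, energy_keV):
        """Interaction-channel probabilities (p_pe, p_inc, p_coh) at a collision."""
        mus = [self.mass_attenuation(material, energy_keV, c) for c in ("pe", "inc", "coh")]
        total = mus[0] + mus[1] + mus[2]
        return tuple(m / total for m in mus)

    def element_coherent_weights(self, material: Material, energy_keV):
        """Per-element relative weights of the coherent channel at ``energy_keV``.

        Used to pick the scattering atom of a Rayleigh event; proportional to
        ``w_i * (mu_coh/rho)_i(E)``.
        """
        syms = [s for s, w in material.fractions.items() if w > 0]
        wts = np.array([
            material.fractions[s] * self.tables[s].interp(energy_keV, "coh")
            for s in syms
        ])
        return syms, wts / wts.sum()


_DEFAULT_LIBRARY: XsecLibrary | None = None


def default_library() -> XsecLibrary:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = XsecLibrary()
    return _DEFAULT_LIBRARY


def mass_attenuation(material: Material, energy_keV, channel: str = "total"):
    """Module-level convenience wrapper over :func:`default_library`."""
    return default_library().mass_attenuation(material, energy_keV, channel)


def linear_attenuation(material: Material, energy_keV):
    return default_library().linear_attenuation(material, energy_keV)


def channel_probabilities(material: Material, energy_keV):
    return default_library().channel_probabilities(material, energy_keV)


# -- fixture loading ------------------------------------------------------

def _read_csv_columns(path_iter, ncols: int):
    rows = []
    for line in path_iter:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if parts[0] == "energy_keV" or parts[0] == "x_invA":
            continue
        rows.append([float(p) for p in parts[:ncols]])
    return np.array(rows, dtype=float).T


def load_element_table_csv(symbol: str, text: Iterable[str]) -> ElementXsecTable:
    e, pe, inc, coh = _read_csv_columns(text, 4)
    return ElementXsecTable(symbol, ATOMIC_NUMBERS[symbol], e, pe, inc, coh)


def load_form_factor_csv(symbol: str, text: Iterable[str]) -> FormFactorTable:
    x, f = _read_csv_columns(text, 2)
    return FormFactorTable(symbol, ATOMIC_NUMBERS[symbol], x, f)


def _load_packaged_xsec() -> dict[str, ElementXsecTable]:
    out = {}
    root = resources.files("mammomc") / "data" / "xsec"
    for sym in ATOMIC_NUMBERS:
        with (root / f"{sym}.csv").open() as fh:
            out[sym] = load_element_table_csv(sym, fh)
    return out


def _load_packaged_ff() -> dict[str, FormFactorTable]:
    out = {}
    root = resources.files("mammomc") / "data" / "formfactor"
    for sym in ATOMIC_NUMBERS:
        with (root / f"{sym}.csv").open() as fh:
            out[sym] = load_form_factor_csv(sym, fh)
    return out
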