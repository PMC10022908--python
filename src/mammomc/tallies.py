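"""Energy-deposition tallies, batch-means errors, repeats, layer fractions.

The per-region tally is the analog of a per-cell energy-deposition (kerma
type, MeV/g) estimator: deposited energy per source photon divided by the
region mass.  Uncertainty comes from batch means: the run is split into
``B`` batches and the relative error is the sample standard deviation of
the batch means divided by ``sqrt(B)`` times the grand mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TallyResult", "finalize", "combine_repeats", "layer_fractions"]

LAYER_ROLES = ("layer1", "layer2", "layer3")


@dataclass
class TallyResult:
    """Finalized per-region deposition tally of one run (or averaged runs)."""

    region_ids: np.ndarray
    region_roles: list[str]
    region_masses_g: np.ndarray
    deposited_MeV_per_photon: np.ndarray
    deposited_MeV_per_g: np.ndarray
    relative_error: np.ndarray
    nps: int
    batches: int
    seed: int
    source_energy_keV: float
    escaped_MeV_per_photon: float = 0.0
    uncollided_escape_fraction: float = 0.0
    escape_fraction: float = 0.0

    @property
    def total_deposited_MeV_per_photon(self) -> float:
        return float(self.deposited_MeV_per_photon.sum())

    @property
    def total_deposited_eV_per_photon(self) -> float:
        return self.total_deposited_MeV_per_photon * 1e6

    def _role_index(self, role: str) -> int:
        try:
            return self.region_roles.index(role)
        except ValueError:
            raise KeyError(f"no region with role {role!r}") from None

    def per_g(self, role: str) -> float:
        return float(self.deposited_MeV_per_g[self._role_index(role)])

    def per_photon(self, role: str) -> float:
        return float(self.deposited_MeV_per_photon[self._role_index(role)])

    def rel_err(self, role: str) -> float:
        return float(self.relative_error[self._role_index(role)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region_id": self.region_ids,
            "role": self.region_roles,
            "mass_g": self.region_masses_g,
            "MeV_per_photon": self.deposited_MeV_per_photon,
            "MeV_per_g": self.deposited_MeV_per_g,
            "rel_err": self.relative_error,
        })

    def to_json_dict(self) -> dict:
        d = {
            "nps": int(self.nps),
            "batches": int(self.batches),
            "seed": int(self.seed),
            "source_energy_keV": self.source_energy_keV,
            "escaped_MeV_per_photon": self.escaped_MeV_per_photon,
            "uncollided_escape_fraction": self.uncollided_escape_fraction,
            "escape_fraction": self.escape_fraction,
            "regions": self.to_frame().to_dict(orient="records"),
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)


def finalize(batch_deposits_keV: np.ndarray, batch_sizes: np.ndarray,
             assembly, seed: int, source_energy_keV: float,
             batch_escaped_keV: np.ndarray | None = None,
             n_uncollided_escaped: int = 0,
             n_escaped: int = 0) -> TallyResult:
    """Reduce per-batch deposition scores to a :class:`TallyResult`.

    ``batch_deposits_keV`` has one row per batch and one column per
    assembly region (total keV deposited in that batch).  At least two
    batches are required for the variance estimate.
    """
    batch_deposits_keV = np.asarray(batch_deposits_keV, dtype=float)
    batch_sizes = np.asarray(batch_sizes)
    B = batch_deposits_keV.shape[0]
    if B < 2:
        raise ValueError("need at least 2 batches for an error estimate")
    nps = int(batch_sizes.sum())

    from .geometry import region_mass  # local import to avoid a cycle

    masses = np.array([region_mass(assembly, r.id) for r in assembly.regions])
    per_photon_MeV = batch_deposits_keV.sum(axis=0) / nps / 1000.0
    batch_means = batch_deposits_keV / batch_sizes[:, None] / 1000.0
    grand = batch_means.mean(axis=0)
    sd = batch_means.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(grand > 0, sd / np.sqrt(B) / np.where(grand > 0, grand, 1.0), 0.0)

    escaped = 0.0
    if batch_escaped_keV is not None:
        escaped = float(np.sum(batch_escaped_keV)) / nps / 1000.0
    return TallyResult(
        region_ids=np.array([r.id for r in assembly.regions]),
        region_roles=[r.role for r in assembly.regions],
        region_masses_g=masses,
        deposited_MeV_per_photon=per_photon_MeV,
        deposited_MeV_per_g=per_photon_MeV / masses,
        relative_error=rel,
        nps=nps,
        batches=B,
        seed=seed,
        source_energy_keV=source_energy_keV,
        escaped_MeV_per_photon=escaped,
        uncollided_escape_fraction=n_uncollided_escaped / nps,
        escape_fraction=n_escaped / nps,
    )


def combine_repeats(results: Sequence[TallyResult]):
    """Average independently seeded repeats of the same configuration.

    Returns ``(mean_result, max_relative_deviation)`` where the deviation
    is ``max_i |x_i - mean| / mean`` of the monitored tally, the total
    deposited energy per photon — the most conservative reading of a
    repeat-to-repeat "deviation rate".
    """
    if len(results) < 2:
        raise ValueError("need at least 2 repeats")
    first = results[0]
    for r in results[1:]:
        if (r.source_energy_keV != first.source_energy_keV
                or r.nps != first.nps
                or list(r.region_ids) != list(first.region_ids)):
            raise ValueError("repeats must share an identical configuration")
    k = len(results)
    totals = np.array([r.total_deposited_MeV_per_photon for r in results])
    mean_total = totals.mean()
    if mean_total <= 0:
        raise ValueError("monitored tally is zero; nothing to compare")
    max_rel_dev = float(np.max(np.abs(totals - mean_total)) / mean_total)

    per_photon = np.mean([r.deposited_MeV_per_photon for r in results], axis=0)
    per_g = np.mean([r.deposited_MeV_per_g for r in results], axis=0)
    # standard error of the mean of independent unbiased runs
    abs_err = np.array([r.relative_error * r.deposited_MeV_per_photon
                        for r in results])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(per_photon > 0,
                       np.sqrt((abs_err ** 2).sum(axis=0)) / k
                       / np.where(per_photon > 0, per_photon, 1.0),
                       0.0)
    mean_result = TallyResult(
        region_ids=first.region_ids.copy(),
        region_roles=list(first.region_roles),
        region_masses_g=first.region_masses_g.copy(),
        deposited_MeV_per_photon=per_photon,
        deposited_MeV_per_g=per_g,
        relative_error=rel,
        nps=first.nps * k,
        batches=first.batches * k,
        seed=first.seed,
        source_energy_keV=first.source_energy_keV,
        escaped_MeV_per_photon=float(np.mean(
            [r.escaped_MeV_per_photon for r in results])),
        uncollided_escape_fraction=float(np.mean(
            [r.uncollided_escape_fraction for r in results])),
        escape_fraction=float(np.mean(
            [r.escape_fraction for r in results])),
    )
    return mean_result, max_rel_dev


def layer_fractions(result: TallyResult, mass_weighted: bool = False):
    """Percentage split of the three-layer deposition, summing to 100.

    By default the split is computed from the per-mass (MeV/g) tallies of
    the three breast layers; ``mass_weighted=True`` uses total deposited
    energy (MeV) instead, as a sensitivity variant.
    """
    vals = []
    for role in LAYER_ROLES:
        i = result._role_index(role)
        v = (result.deposited_MeV_per_photon[i] if mass_weighted
             else result.deposited_MeV_per_g[i])
        vals.append(v)
    vals = np.asarray(vals, dtype=float)
    total = vals.sum()
    if total <= 0:
        raise ValueError("zero total layer deposition")
    return tuple(100.0 * v / total for v in vals)
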