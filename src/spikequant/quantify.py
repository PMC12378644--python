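"""Recovery-ratio calculus and absolute abundance estimation.

Per spiked standard: genome copies recovered S_r = S_s / S_p and
recovery ratio R = S_r / S_a. The per-sample combined R converts marker
read counts into gene molecules G_a = G_s / R, then into haploid genome
equivalents per liter (divide by volume filtered) and ploidy-adjusted
cells (divide by ploidy). The detection limit is the volumetric
abundance corresponding to a single annotated read, 1 / (R x volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import MARKER_NAMES, STANDARD_CLASS

COMBINE_METHODS = ("geometric", "arithmetic", "pooled")

#: combined recovery at or above this aborts the sample (miscounting)
MAX_SANE_RECOVERY = 2.0


class RecoveryWarning(UserWarning):
    """Recovery ratio looks implausible but is not fatal."""


class SampleAbortedError(ValueError):
    """Sample-level quantification is unsafe (e.g. R >= 2)."""


def standard_recovery(s_s: float, s_p: float) -> float:
    """Genome copies of a standard recovered: S_r = S_s / S_p."""
    if s_p < 1:
        raise ValueError("s_p must be >= 1")
    if s_s < 0:
        raise ValueError("s_s must be >= 0")
    return s_s / s_p

def recovery_ratio(s_r: float, s_a: float) -> float:
    """Proportion of added standard genome copies recovered: R = S_r / S_a."""
    if s_a <= 0:
        raise ValueError("s_a must be > 0")
    r = s_r / s_a
    if r > 1:
        warnings.warn(
            f"recovery ratio {r:.3g} > 1: more standard recovered than added",
            RecoveryWarning,
            stacklevel=2,
        )
    return r


@dataclass(frozen=True)
class StandardRecovery:
    """Recovery bookkeeping for one standard in one sample."""

    standard_id: str
    s_s: float
    s_p: float
    s_a: float

    @property
    def s_r(self) -> float:
        return standard_recovery(self.s_s, self.s_p)

    @property
    def r(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RecoveryWarning)
            return recovery_ratio(self.s_r, self.s_a)


def combine_recoveries(
    per_standard: Sequence[StandardRecovery] | Sequence[float],
    method: str = "geometric",
) -> float:
    """Combine per-standard recovery ratios into one per-sample R.

    Default is the geometric mean (multiplicative noise model);
    ``arithmetic`` and ``pooled`` (sum S_s / sum S_p*S_a) are available.
    Zero or non-finite ratios are dropped with a warning; a max/min
    dispersion above 2 warns that a spike may have failed.
    """
    if method not in COMBINE_METHODS:
        raise ValueError(f"method must be one of {COMBINE_METHODS}")
    items = list(per_standard)
    if not items:
        raise ValueError("no recovery ratios supplied")
    structured = isinstance(items[0], StandardRecovery)
    rs = np.array([x.r for x in items] if structured else [float(x) for x in items])
    good = np.isfinite(rs) & (rs > 0)
    if not good.any():
        raise ValueError("all recovery ratios are zero or missing")
    if not good.all():
        warnings.warn(
            f"dropping {int((~good).sum())} zero/non-finite recovery ratio(s)",
            RecoveryWarning,
            stacklevel=2,
        )
    rs = rs[good]
    if rs.max() / rs.min() > 2:
        warnings.warn(
            f"recovery dispersion max/min = {rs.max() / rs.min():.2f} > 2; "
            "a spike may have failed",
            RecoveryWarning,
            stacklevel=2,
        )
    if method == "geometric":
        return float(np.exp(np.mean(np.log(rs))))
    if method == "arithmetic":
        return float(np.mean(rs))
    if not structured:
        raise ValueError("pooled combination needs StandardRecovery records")
    kept = [x for x, g in zip(items, good) if g]
    return float(sum(x.s_s for x in kept) / sum(x.s_p * x.s_a for x in kept))


def gene_abundance(g_s: float, r: float) -> float:
    """Gene molecules in the sample: G_a = G_s / R."""
    if r <= 0:
        raise ValueError("recovery ratio must be > 0; sample must be flagged, not zeroed")
    if g_s < 0:
        raise ValueError("g_s must be >= 0")
    return g_s / r


def volumetric_abundance(g_a: float, volume_liters: float) -> float:
    """Haploid genome equivalents per liter: G_a / volume filtered."""
    if volume_liters <= 0:
        raise ValueError("volume_liters must be > 0")
    return g_a / volume_liters


def detection_limit(r: float, volume_liters: float) -> float:
    """Volumetric abundance at a single annotated read: 1 / (R x volume)."""
    if r <= 0:
        raise ValueError("recovery ratio must be > 0")
    if volume_liters <= 0:
        raise ValueError("volume_liters must be > 0")
    return 1.0 / (r * volume_liters)


def cells_from_haploid(genome_equivalents: float, ploidy: float) -> float:
    """Cells from haploid genome equivalents (diploid: half the equivalents)."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    return genome_equivalents / ploidy


@dataclass
class RecoveryEstimate:
    """Per-sample recovery summary."""

    sample_id: str
    per_standard: dict[str, StandardRecovery]
    r_combined: float
    method: str

    @property
    def dispersion(self) -> float:
        rs = [x.r for x in self.per_standard.values() if x.r > 0]
        return max(rs) / min(rs) if rs else float("nan")


def estimate_recovery(
    counts: pd.DataFrame,
    standards_meta: pd.DataFrame,
    sample_id: str,
    method: str = "geometric",
) -> RecoveryEstimate:
    """Recovery estimate for one sample from its count table.

    ``counts`` rows with reference_class == "standard_gene" supply S_s per
    standard; ``standards_meta`` (sample_id, standard_id, s_p, s_a)
    supplies the denominators.
    """
    meta = standards_meta[standards_meta["sample_id"] == sample_id]
    if meta.empty:
        raise ValueError(f"no standard metadata for sample {sample_id!r}")
    std_counts = counts[
        (counts["sample_id"] == sample_id)
        & (counts["reference_class"] == STANDARD_CLASS)
    ]
    s_s = dict(zip(std_counts["reference_id"], std_counts["count"]))
    per_standard = {
        row.standard_id: StandardRecovery(
            standard_id=row.standard_id,
            s_s=float(s_s.get(row.standard_id, 0)),
            s_p=float(row.s_p),
            s_a=float(row.s_a),
        )
        for row in meta.itertuples()
    }
    r_combined = combine_recoveries(list(per_standard.values()), method=method)
    if r_combined > 1:
        warnings.warn(
            f"sample {sample_id}: combined recovery {r_combined:.3g} > 1 — "
            "more standard recovered than added",
            RecoveryWarning,
            stacklevel=2,
        )
    if r_combined >= MAX_SANE_RECOVERY:
        raise SampleAbortedError(
            f"sample {sample_id}: combined recovery {r_combined:.3g} >= "
            f"{MAX_SANE_RECOVERY}; aborting sample"
        )
    return RecoveryEstimate(sample_id, per_standard, r_combined, method)


def recovery_table(estimates: Iterable[RecoveryEstimate]) -> pd.DataFrame:
    rows = []
    for est in estimates:
        for st in est.per_standard.values():
            rows.append(
                {
                    "sample_id": est.sample_id,
                    "standard_id": st.standard_id,
                    "s_s": st.s_s,
                    "s_p": st.s_p,
                    "s_a": st.s_a,
                    "s_r": st.s_r,
                    "r": st.r,
                    "r_combined": est.r_combined,
                    "dispersion": est.dispersion,
                    "method": est.method,
                }
            )
    return pd.DataFrame(rows)


def abundance_table(
    counts: pd.DataFrame,
    estimates: Mapping[str, RecoveryEstimate],
    samples_meta: pd.DataFrame,
    ploidy: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-sample, per-taxon, per-marker absolute abundances.

    A zero count reports abundance 0 alongside the sample's detection
    limit, so absence is never confused with non-detection. Default
    ploidy is 1: abundances are haploid genome equivalents unless a
    ploidy table says otherwise.
    """
    volumes = dict(zip(samples_meta["sample_id"], samples_meta["volume_liters"]))
    ploidy = ploidy or {}
    marker_rows = counts[counts["reference_class"].isin(MARKER_NAMES)]
    rows = []
    for row in marker_rows.itertuples():
        est = estimates.get(row.sample_id)
        if est is None:
            continue
        vol = volumes[row.sample_id]
        g_a = gene_abundance(float(row.count), est.r_combined)
        volumetric = volumetric_abundance(g_a, vol)
        p = int(ploidy.get(row.taxon_id, 1))
        rows.append(
            {
                "sample_id": row.sample_id,
                "taxon_id": row.taxon_id,
                "marker_name": row.reference_class,
                "g_s": float(row.count),
                "g_a": g_a,
                "haploid_equivalents_per_liter": volumetric,
                "ploidy": p,
                "cells_per_liter": cells_from_haploid(volumetric, p),
                "detection_limit_per_liter": detection_limit(est.r_combined, vol),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "taxon_id",
            "marker_name",
            "g_s",
            "g_a",
            "haploid_equivalents_per_liter",
            "ploidy",
            "cells_per_liter",
            "detection_limit_per_liter",
        ],
    )


def quantify_samples(
    counts: pd.DataFrame,
    samples_meta: pd.DataFrame,
    standards_meta: pd.DataFrame,
    method: str = "geometric",
    ploidy: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run recovery estimation + abundance conversion for every sample.

    Returns (recovery table, abundance table).
    """
    estimates: dict[str, RecoveryEstimate] = {}
    for sample_id in samples_meta["sample_id"]:
        estimates[sample_id] = estimate_recovery(
            counts, standards_meta, sample_id, method=method
        )
    rec = recovery_table(estimates.values())
    abund = abundance_table(counts, estimates, samples_meta, ploidy=ploidy)
    return rec, abund
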