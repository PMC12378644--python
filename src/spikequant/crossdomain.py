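"""Cross-domain eukaryotic phytoplankton estimators.

Two routes to eukaryote haploid genome equivalents from psbO counts:

* direct — apply the sample's recovery ratio to psbO reads exactly as
  for recA (inherits any psbO annotation undercount as a bias);
* anchored — scale the cyanobacterial recA-based absolute abundance by
  the ratio of eukaryotic to cyanobacterial psbO reads. Any common
  multiplicative psbO undercount cancels in the ratio, so this route
  stays unbiased when the undercount affects both groups equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .quantify import RecoveryEstimate, detection_limit, gene_abundance, volumetric_abundance

ESTIMATORS = ("direct", "anchored", "both")


@dataclass
class CrossDomainInput:
    """Per-sample ingredients for the cyanobacteria-anchored estimator.

    ``g_reca_cyano`` is the recovered cyanobacterial recA absolute
    abundance (molecules or per-liter; the unit is carried through
    unchanged since the psbO ratio is dimensionless).
    """

    sample_id: str
    g_reca_cyano: float
    psbo_cyano: float
    psbo_euk_by_taxon: dict[str, float] = field(default_factory=dict)
    unit: str = "per_liter"

    def __post_init__(self) -> None:
        if self.g_reca_cyano < 0 or self.psbo_cyano < 0:
            raise ValueError("counts must be >= 0")
        if any(v < 0 for v in self.psbo_euk_by_taxon.values()):
            raise ValueError("counts must be >= 0")


@dataclass
class AnchoredResult:
    sample_id: str
    per_taxon: dict[str, float]
    unit: str

    @property
    def total(self) -> float:
        return sum(self.per_taxon.values())


def euk_abundance_direct(
    psbo_euk_reads: float, r_combined: float, volume_liters: float
) -> float:
    """Eukaryote haploid genome equivalents per liter, recovery-ratio route."""
    return volumetric_abundance(gene_abundance(psbo_euk_reads, r_combined), volume_liters)


def euk_abundance_anchored(inp: CrossDomainInput) -> AnchoredResult:
    """Cyanobacteria-anchored estimate: G_recA_cyano x psbO_euk / psbO_cyano."""
    if inp.psbo_cyano <= 0:
        raise ValueError(
            f"sample {inp.sample_id}: zero cyanobacterial psbO reads; anchored "
            "estimator undefined — flag the sample and use the direct estimate"
        )
    per_taxon = {
        taxon: inp.g_reca_cyano * reads / inp.psbo_cyano
        for taxon, reads in inp.psbo_euk_by_taxon.items()
    }
    return AnchoredResult(inp.sample_id, per_taxon, inp.unit)


def crossdomain_input_from_tables(
    counts: pd.DataFrame,
    abundance: pd.DataFrame,
    domains: Mapping[str, str],
    sample_id: str,
) -> CrossDomainInput:
    """Assemble the anchored-estimator input for one sample.

    ``counts`` supplies psbO read counts; ``abundance`` supplies the
    recA-based cyanobacterial absolute abundance (per liter).
    """
    cyano = {t for t, d in domains.items() if d == "cyanobacteria"}
    euks = {t for t, d in domains.items() if d == "eukaryote_phytoplankton"}
    ab = abundance[(abundance["sample_id"] == sample_id)]
    g_reca_cyano = float(
        ab[(ab["marker_name"] == "recA") & (ab["taxon_id"].isin(cyano))][
            "haploid_equivalents_per_liter"
        ].sum()
    )
    psbo = counts[
        (counts["sample_id"] == sample_id) & (counts["reference_class"] == "psbO")
    ]
    psbo_cyano = float(psbo[psbo["taxon_id"].isin(cyano)]["count"].sum())
    psbo_euk = {
        str(row.taxon_id): float(row.count)
        for row in psbo[psbo["taxon_id"].isin(euks)].itertuples()
    }
    return CrossDomainInput(sample_id, g_reca_cyano, psbo_cyano, psbo_euk)


def estimate_eukaryotes(
    counts: pd.DataFrame,
    abundance: pd.DataFrame,
    estimates: Mapping[str, RecoveryEstimate],
    samples_meta: pd.DataFrame,
    domains: Mapping[str, str],
    estimator: str = "both",
) -> pd.DataFrame:
    """Per-sample per-taxon eukaryote abundance table for both estimators.

    Output columns: sample_id, taxon_id, estimator,
    haploid_equivalents_per_liter, psbo_reads, detection_limit_per_liter,
    flagged. When the anchored estimator is undefined (no cyanobacterial
    psbO reads) its rows carry flagged=anchored_undefined and NaN values.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    volumes = dict(zip(samples_meta["sample_id"], samples_meta["volume_liters"]))
    rows = []
    for sample_id in samples_meta["sample_id"]:
        inp = crossdomain_input_from_tables(counts, abundance, domains, sample_id)
        est = estimates[sample_id]
        vol = volumes[sample_id]
        limit = detection_limit(est.r_combined, vol)
        if estimator in ("direct", "both"):
            for taxon, reads in sorted(inp.psbo_euk_by_taxon.items()):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "taxon_id": taxon,
                        "estimator": "direct",
                        "haploid_equivalents_per_liter": euk_abundance_direct(
                            reads, est.r_combined, vol
                        ),
                        "psbo_reads": reads,
                        "detection_limit_per_liter": limit,
                        "flagged": "",
                    }
                )
        if estimator in ("anchored", "both"):
            if inp.psbo_cyano > 0:
                res = euk_abundance_anchored(inp)
                for taxon, value in sorted(res.per_taxon.items()):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "taxon_id": taxon,
                            "estimator": "anchored",
                            "haploid_equivalents_per_liter": value,
                            "psbo_reads": inp.psbo_euk_by_taxon[taxon],
                            "detection_limit_per_liter": limit,
                            "flagged": "",
                        }
                    )
            else:
                for taxon, reads in sorted(inp.psbo_euk_by_taxon.items()):
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "taxon_id": taxon,
                            "estimator": "anchored",
                            "haploid_equivalents_per_liter": float("nan"),
                            "psbo_reads": reads,
                            "detection_limit_per_liter": limit,
                            "flagged": "anchored_undefined",
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "taxon_id",
            "estimator",
            "haploid_equivalents_per_liter",
            "psbo_reads",
            "detection_limit_per_liter",
            "flagged",
        ],
    )
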