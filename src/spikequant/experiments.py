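"""Replicated simulation experiments for method verification.

These drive the synthetic generator through the full pipeline and
measure estimator behaviour: end-to-end parameter recovery, the psbO
undercount bias and its cancellation by the cyanobacteria-anchored
estimator, and detection-limit scaling with sequencing depth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import crossdomain, matcher, quantify, synthetic


#: compact roster for recovery experiments: all four domains represented,
#: genomes small enough that even the least abundant taxon accumulates a
#: few hundred expected marker reads over a 20-sample transect
RECOVERY_ROSTER = dict(
    genome_length=20_000,
    taxa=[
        {"taxon_id": "bact1", "domain_label": "bacteria"},
        {"taxon_id": "bact2", "domain_label": "bacteria"},
        {"taxon_id": "bact3", "domain_label": "bacteria"},
        {"taxon_id": "arch1", "domain_label": "archaea"},
        {"taxon_id": "cyano1", "domain_label": "cyanobacteria"},
        {"taxon_id": "euk1", "domain_label": "eukaryote_phytoplankton"},
        {"taxon_id": "euk2", "domain_label": "eukaryote_phytoplankton", "ploidy": 2},
    ],
)


def parameter_recovery_experiment(
    n_samples: int = 20,
    n_reads: int = 100_000,
    seed: int = 0,
    use_matcher: bool = True,
    config_overrides: dict | None = None,
) -> pd.DataFrame:
    """Simulate a transect and push it through the whole pipeline.

    Returns one row per (sample, taxon, marker): the estimated and true
    haploid genome equivalents per liter plus the closed-form expected
    marker read count (used to select well-covered points).

    ``use_matcher=False`` counts reads with the simulator's annotated
    tallies instead of classifying sequences — same distribution, much
    faster; the matcher route is the true end-to-end path.
    """
    overrides = {**RECOVERY_ROSTER, **(config_overrides or {})}
    cfg = synthetic.default_config(
        n_samples=n_samples,
        n_reads=n_reads,
        seed=seed,
        abundance_range=[1e7, 1e9],
        force_endpoints=True,
        **overrides,
    )
    tr = synthetic.build_transect(cfg)
    refs = matcher.references_from_transect(tr) if use_matcher else None

    all_counts = []
    expected = {}
    for sample, truth, stds in zip(tr.samples, tr.truths, tr.standards_by_sample):
        if use_matcher:
            reads, _ = synthetic.simulate_reads(truth, stds, sample)
            counts = matcher.count_hits(reads, refs, sample_id=sample.sample_id)
        else:
            counts = synthetic.simulate_counts(truth, stds, sample)
        all_counts.append(counts)
        exp = synthetic.expected_counts(truth, stds, sample)
        for row in exp.itertuples():
            expected[(row.sample_id, row.reference_id)] = row.count
    counts = pd.concat(all_counts, ignore_index=True)

    _, abund = quantify.quantify_samples(counts, tr.sample_table(), tr.standard_table())
    merged = abund.merge(tr.truth_table(), on=["sample_id", "taxon_id"])
    merged["expected_reads"] = [
        expected[(row.sample_id, f"{row.marker_name}|{row.taxon_id}")]
        for row in merged.itertuples()
    ]
    return merged[
        [
            "sample_id",
            "taxon_id",
            "marker_name",
            "g_s",
            "expected_reads",
            "haploid_equivalents_per_liter",
            "true_haploid_equivalents_per_liter",
        ]
    ]


def undercount_bias_experiment(
    n_replicates: int = 50,
    n_reads: int = 300_000,
    psbo_sensitivity: float = 0.72,
    seed: int = 0,
) -> dict[str, float]:
    """Replicated single-sample runs with psbO annotation thinning.

    The thinning applies to cyanobacterial and eukaryotic psbO alike.
    Returns pooled through-origin slopes of (estimate vs truth) for the
    eukaryote taxa under both estimators.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = synthetic.default_config(
            n_samples=1,
            n_reads=n_reads,
            seed=seed + rep,
            sensitivity={"psbO": psbo_sensitivity},
            abundance_range=[1e8, 1e9],
            force_endpoints=False,
        )
        tr = synthetic.build_transect(cfg)
        counts = synthetic.simulate_counts(
            tr.truths[0], tr.standards_by_sample[0], tr.samples[0]
        )
        _, abund = quantify.quantify_samples(counts, tr.sample_table(), tr.standard_table())
        estimates = {
            "sample001": quantify.estimate_recovery(counts, tr.standard_table(), "sample001")
        }
        euk = crossdomain.estimate_eukaryotes(
            counts, abund, estimates, tr.sample_table(), tr.domain_map(), estimator="both"
        )
        truth = tr.truth_table().set_index("taxon_id")["true_haploid_equivalents_per_liter"]
        euk = euk.assign(truth=euk["taxon_id"].map(truth), replicate=rep)
        rows.append(euk)
    pooled = pd.concat(rows, ignore_index=True)

    def _slope(frame: pd.DataFrame) -> float:
        x = frame["truth"].to_numpy()
        y = frame["haploid_equivalents_per_liter"].to_numpy()
        return float((x * y).sum() / (x * x).sum())

    return {
        "direct": _slope(pooled[pooled["estimator"] == "direct"]),
        "anchored": _slope(pooled[pooled["estimator"] == "anchored"]),
        "n_points": int(len(pooled) / 2),
    }


def depth_scaling_experiment(
    n_replicates: int = 50,
    base_reads: int = 50_000,
    depth_factor: int = 13,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical detection-limit ratio between base and deep sequencing.

    Each replicate estimates the recovery ratio at ``base_reads`` and at
    ``depth_factor x base_reads`` from fresh multinomial draws, and
    converts both to detection limits. Returns the mean limit ratio
    (expected to equal depth_factor).
    """
    cfg = synthetic.default_config(n_samples=1, n_reads=base_reads, seed=seed)
    tr = synthetic.build_transect(cfg)
    truth, stds, sample = tr.truths[0], tr.standards_by_sample[0], tr.samples[0]
    volume = sample.volume_liters
    ratios = []
    limits_base = []
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        shallow = dataclasses.replace(sample, seed=int(rng.integers(2**31)))
        deep = dataclasses.replace(
            shallow, n_reads=base_reads * depth_factor, seed=int(rng.integers(2**31))
        )
        limits = []
        for spec in (shallow, deep):
            counts = synthetic.simulate_counts(truth, stds, spec)
            est = quantify.estimate_recovery(counts, tr.standard_table(), "sample001")
            limits.append(quantify.detection_limit(est.r_combined, volume))
        ratios.append(limits[0] / limits[1])
        limits_base.append(limits[0])
    return {
        "mean_limit_ratio": float(np.mean(ratios)),
        "mean_base_limit": float(np.mean(limits_base)),
        "depth_factor": depth_factor,
        "n_replicates": n_replicates,
    }
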