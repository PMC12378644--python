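"""Synthetic spiked-metagenome generator.

Builds a multi-sample transect of communities with known ("truth")
abundances, spikes each sample with genomic internal standards at a
configurable fraction of total DNA mass, and simulates merged shotgun
reads by a two-step draw: source genome chosen with probability
proportional to (copies x genome_length), start position uniform.

A read is a latent hit on a locus iff it overlaps the locus by at least
half the read length; a latent hit becomes an *annotated* hit with a
per-marker sensitivity probability (emulating database-driven
undercounting of some markers). ``simulate_counts`` draws the identical
count distribution directly from a multinomial without materializing
read sequences, for cheap replicated experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    DOMAIN_MARKERS,
    STANDARD_CLASS,
    CommunityTruth,
    MarkerLocus,
    SampleSpec,
    StandardSpec,
    TaxonSpec,
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length n."""
    return _BASE_BYTES[rng.integers(0, 4, n, dtype=np.uint8)].tobytes().decode("ascii")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of equal positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(np.count_nonzero(xa == xb)) / len(a)


def _diverged_seq(
    rng: np.random.Generator,
    length: int,
    others: list[str],
    max_identity: float,
    tries: int = 100,
) -> str:
    """Random sequence whose positional identity to every sequence in
    ``others`` (of the same length) stays at or below ``max_identity``."""
    for _ in range(tries):
        seq = random_dna(rng, length)
        if all(
            len(o) != length or pairwise_identity(seq, o) <= max_identity for o in others
        ):
            return seq
    raise RuntimeError("could not generate sufficiently diverged sequence")


def min_overlap(read_length: int) -> int:
    """Smallest integer overlap satisfying overlap >= read_length / 2."""
    return (read_length + 1) // 2


def n_hit_starts(start: int, end: int, genome_length: int, read_length: int) -> int:
    """Number of read start positions producing a latent hit on [start, end).

    A read [r, r+L) hits iff its overlap with the locus is >= L/2; valid
    starts form the closed interval [start-L+h, end-h] clipped to
    [0, genome_length-L], with h = ceil(L/2). A locus shorter than h can
    never be hit.
    """
    h = min_overlap(read_length)
    if end - start < h:
        return 0
    lo = max(start - read_length + h, 0)
    hi = min(end - h, genome_length - read_length)
    return max(0, hi - lo + 1)


# ---------------------------------------------------------------------------
# transect construction


@dataclass
class Transect:
    """A simulated transect: per-sample specs, truths, and standards.

    ``standards_by_sample`` holds one StandardSpec list per sample because
    the spike dose (s_a) is chosen per sample to hit the target DNA-mass
    fraction; the underlying standard genomes are shared.
    """

    samples: list[SampleSpec]
    truths: list[CommunityTruth]
    standards_by_sample: list[list[StandardSpec]]
    config: dict = field(default_factory=dict)

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sample_id": s.sample_id, "volume_liters": s.volume_liters} for s in self.samples]
        )

    def standard_table(self) -> pd.DataFrame:
        rows = []
        for sample, stds in zip(self.samples, self.standards_by_sample):
            for st in stds:
                rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "standard_id": st.standard_id,
                        "s_p": st.s_p,
                        "s_a": st.s_a,
                    }
                )
        return pd.DataFrame(rows)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for sample, truth in zip(self.samples, self.truths):
            for t in truth.taxa:
                rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "taxon_id": t.taxon_id,
                        "domain_label": t.domain_label,
                        "ploidy": t.ploidy,
                        "true_cells_per_liter": t.true_cells_per_liter,
                        "true_haploid_equivalents_per_liter": t.true_cells_per_liter
                        * t.ploidy,
                    }
                )
        return pd.DataFrame(rows)

    def domain_map(self) -> dict[str, str]:
        return {t.taxon_id: t.domain_label for t in self.truths[0].taxa}


DEFAULT_TAXA = (
    [{"taxon_id": f"bact{i}", "domain_label": "bacteria"} for i in range(1, 7)]
    + [{"taxon_id": "arch1", "domain_label": "archaea"}]
    + [{"taxon_id": f"cyano{i}", "domain_label": "cyanobacteria"} for i in (1, 2)]
    + [
        {"taxon_id": f"euk{i}", "domain_label": "eukaryote_phytoplankton", "ploidy": p}
        for i, p in ((1, 1), (2, 2), (3, 1))
    ]
)

DEFAULT_STANDARDS = [
    {"standard_id": f"std{c}", "n_genes": 20, "gene_length": 1000} for c in "ABC"
]


def default_config(**overrides) -> dict:
    """A representative desk-scale transect configuration."""
    cfg = {
        "seed": 0,
        "n_samples": 3,
        "volume_liters": 1.0,
        "n_reads": 50_000,
        "read_length": 250,
        "error_rate": 0.0,
        "dosing_fraction": 0.01,
        "abundance_range": [1.0e7, 1.0e9],
        "force_endpoints": True,
        "marker_length": 1000,
        "genome_length": 40_000,
        "sensitivity": {},
        "taxa": [dict(t) for t in DEFAULT_TAXA],
        "standards": [dict(s) for s in DEFAULT_STANDARDS],
    }
    cfg.update(overrides)
    return cfg


def _build_roster(cfg: dict, rng: np.random.Generator):
    """Generate genome sequences with embedded, mutually diverged loci."""
    marker_len = int(cfg.get("marker_length", 1000))
    read_len = int(cfg["read_length"])
    gap = max(read_len, 1)

    marker_seqs: list[str] = []  # taxa marker sequences, for divergence control
    taxa_layout = []
    for tx in cfg["taxa"]:
        domain = tx["domain_label"]
        genome_len = int(tx.get("genome_length", cfg.get("genome_length", 40_000)))
        genome = bytearray(random_dna(rng, genome_len).encode())
        markers = []
        pos = 2 * gap
        for name in DOMAIN_MARKERS[domain]:
            seq = _diverged_seq(rng, marker_len, marker_seqs, max_identity=0.80)
            marker_seqs.append(seq)
            if pos + marker_len + gap > genome_len:
                raise ValueError(f"genome of {tx['taxon_id']} too short for its markers")
            genome[pos : pos + marker_len] = seq.encode()
            markers.append(MarkerLocus(name, pos, pos + marker_len, seq))
            pos += marker_len + gap
        taxa_layout.append(
            {
                "taxon_id": tx["taxon_id"],
                "domain_label": domain,
                "genome_length": genome_len,
                "ploidy": int(tx.get("ploidy", 1)),
                "markers": markers,
                "genome_sequence": genome.decode(),
            }
        )

    standards_layout = []
    for st in cfg["standards"]:
        n_genes = int(st.get("n_genes", 20))
        gene_len = int(st.get("gene_length", 1000))
        genome_len = int(
            st.get("genome_length", 2 * gap + n_genes * (gene_len + gap) + gap)
        )
        genome = bytearray(random_dna(rng, genome_len).encode())
        loci = []
        pos = gap
        for j in range(n_genes):
            # standard genes only need strong divergence from community markers
            seq = (
                _diverged_seq(rng, gene_len, marker_seqs, max_identity=0.60)
                if gene_len == marker_len
                else random_dna(rng, gene_len)
            )
            if pos + gene_len + 1 > genome_len:
                raise ValueError(f"standard {st['standard_id']} genome too short")
            genome[pos : pos + gene_len] = seq.encode()
            loci.append(MarkerLocus("gene", pos, pos + gene_len, seq))
            pos += gene_len + gap
        standards_layout.append(
            {
                "standard_id": st["standard_id"],
                "genome_length": genome_len,
                "s_p": n_genes,
                "gene_loci": loci,
                "genome_sequence": genome.decode(),
            }
        )
    return taxa_layout, standards_layout


def build_transect(config: dict) -> Transect:
    """Construct a deterministic multi-sample transect from a config dict.

    Standard doses (s_a) are chosen per sample so that total standard DNA
    mass is the configured ``dosing_fraction`` of total DNA mass, with
    mass taken proportional to copies x genome_length.
    """
    cfg = dict(config)
    if not cfg.get("taxa"):
        raise ValueError("taxon roster must not be empty")
    frac = float(cfg.get("dosing_fraction", 0.01))
    if not (0 < frac < 0.5):
        raise ValueError("dosing_fraction must lie in (0, 0.5)")
    n_samples = int(cfg.get("n_samples", 1))
    lo, hi = (float(v) for v in cfg.get("abundance_range", [1e7, 1e9]))
    if not (0 < lo <= hi):
        raise ValueError("abundance_range must be positive and ordered")
    volume = float(cfg.get("volume_liters", 1.0))
    read_len = int(cfg.get("read_length", 250))

    rng = np.random.default_rng(int(cfg.get("seed", 0)))
    taxa_layout, standards_layout = _build_roster(cfg, rng)

    samples: list[SampleSpec] = []
    truths: list[CommunityTruth] = []
    standards_by_sample: list[list[StandardSpec]] = []
    for i in range(n_samples):
        sample_id = f"sample{i+1:03d}"
        abund = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), len(taxa_layout))
        if cfg.get("force_endpoints", False) and len(taxa_layout) >= 2:
            abund[0], abund[1] = lo, hi
        taxa = [
            TaxonSpec(true_cells_per_liter=float(a), **layout)
            for layout, a in zip(taxa_layout, abund)
        ]
        community_mass = sum(
            t.true_cells_per_liter * volume * t.ploidy * t.genome_length for t in taxa
        )
        total_std_mass = frac / (1.0 - frac) * community_mass
        per_std_mass = total_std_mass / len(standards_layout)
        stds = [
            StandardSpec(s_a=per_std_mass / layout["genome_length"], **layout)
            for layout in standards_layout
        ]
        samples.append(
            SampleSpec(
                sample_id=sample_id,
                volume_liters=volume,
                n_reads=int(cfg.get("n_reads", 50_000)),
                read_length=read_len,
                per_marker_sensitivity=dict(cfg.get("sensitivity", {}) or {}),
                seed=int(rng.integers(0, 2**31 - 1)),
                error_rate=float(cfg.get("error_rate", 0.0)),
            )
        )
        truths.append(CommunityTruth(sample_id=sample_id, taxa=taxa))
        standards_by_sample.append(stds)
    return Transect(samples, truths, standards_by_sample, config=cfg)


# ---------------------------------------------------------------------------
# read / count simulation


@dataclass(frozen=True)
class ReadRecord:
    """One simulated merged read with its latent-source tags (tests only)."""

    read_id: str
    sequence: str
    source_id: str
    hit_locus: str = ""  # reference_id of the latent hit, "" if none
    annotated: bool = False

    @property
    def header(self) -> str:
        hit = self.hit_locus or "-"
        return f"{self.read_id} src={self.source_id} hit={hit} ann={int(self.annotated)}"


@dataclass(frozen=True)
class _Source:
    source_id: str
    kind: str  # "taxon" | "standard"
    genome_length: int
    copies: float
    sequence: str
    loci: tuple  # (ref_id, ref_class, start, end, sensitivity)


def _sources(
    truth: CommunityTruth,
    standards: Iterable[StandardSpec],
    sample: SampleSpec,
) -> list[_Source]:
    out = []
    std_sens = sample.sensitivity(STANDARD_CLASS)
    for t in truth.taxa:
        loci = tuple(
            (
                f"{m.marker_name}|{t.taxon_id}",
                m.marker_name,
                m.start,
                m.end,
                sample.sensitivity(m.marker_name),
            )
            for m in t.markers
        )
        copies = t.true_cells_per_liter * sample.volume_liters * t.ploidy
        out.append(
            _Source(t.taxon_id, "taxon", t.genome_length, copies, t.genome_sequence, loci)
        )
    for st in standards:
        loci = tuple(
            (
                f"{st.standard_id}|g{j:03d}",
                STANDARD_CLASS,
                g.start,
                g.end,
                std_sens,
            )
            for j, g in enumerate(st.gene_loci)
        )
        out.append(
            _Source(
                st.standard_id, "standard", st.genome_length, st.s_a, st.genome_sequence, loci
            )
        )
    return out


def _count_frame(
    truth: CommunityTruth,
    standards: Iterable[StandardSpec],
    sample_id: str,
    latent: dict[str, float],
    annotated: dict[str, float],
    value_dtype=int,
) -> pd.DataFrame:
    """All-aggregates count frame (zero-filled) in a canonical row order."""
    rows = []
    for st in standards:
        key = st.standard_id
        rows.append(
            {
                "sample_id": sample_id,
                "reference_class": STANDARD_CLASS,
                "reference_id": st.standard_id,
                "taxon_id": "",
                "latent_count": latent.get(key, 0),
                "count": annotated.get(key, 0),
            }
        )
    for t in truth.taxa:
        for m in t.markers:
            key = f"{m.marker_name}|{t.taxon_id}"
            rows.append(
                {
                    "sample_id": sample_id,
                    "reference_class": m.marker_name,
                    "reference_id": key,
                    "taxon_id": t.taxon_id,
                    "latent_count": latent.get(key, 0),
                    "count": annotated.get(key, 0),
                }
            )
    df = pd.DataFrame(rows)
    df["latent_count"] = df["latent_count"].astype(value_dtype)
    df["count"] = df["count"].astype(value_dtype)
    return df


def _check_read_length(sources: list[_Source], read_length: int) -> None:
    shortest = min(s.genome_length for s in sources)
    if read_length > shortest:
        raise ValueError(
            f"read_length {read_length} exceeds shortest genome length {shortest}"
        )


def simulate_reads(
    truth: CommunityTruth,
    standards: list[StandardSpec],
    sample: SampleSpec,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate merged reads for one sample.

    Returns the reads (with latent-source tags used only by tests) and a
    TrueCounts table recording, per reference aggregate, the latent
    overlap events and the annotated hits that survived the per-marker
    sensitivity thinning.
    """
    sources = _sources(truth, standards, sample)
    weights = np.array([s.copies * s.genome_length for s in sources], dtype=float)
    total_mass = weights.sum()
    if total_mass <= 0:
        raise ValueError("total DNA mass must be > 0")
    L = sample.read_length
    _check_read_length(sources, L)
    rng = np.random.default_rng(sample.seed)
    per_source = rng.multinomial(sample.n_reads, weights / total_mass)

    h = min_overlap(L)
    reads: list[ReadRecord] = []
    latent: dict[str, int] = {}
    annotated: dict[str, int] = {}
    read_no = 0
    for src, n in zip(sources, per_source):
        if n == 0:
            continue
        starts = rng.integers(0, src.genome_length - L + 1, size=n)
        hit_ref = np.full(n, -1)  # index into src.loci
        ann = np.zeros(n, dtype=bool)
        for li, (ref_id, ref_class, s0, e0, sens) in enumerate(src.loci):
            if e0 - s0 < h:  # locus too short to ever satisfy the overlap rule
                continue
            lo = s0 - L + h
            hi = e0 - h
            mask = (starts >= lo) & (starts <= hi)
            k = int(mask.sum())
            if k == 0:
                continue
            hit_ref[mask] = li
            keep = rng.random(k) < sens if sens < 1.0 else np.ones(k, dtype=bool)
            ann[np.flatnonzero(mask)[keep]] = True
            agg = ref_id if ref_class != STANDARD_CLASS else src.source_id
            latent[agg] = latent.get(agg, 0) + k
            annotated[agg] = annotated.get(agg, 0) + int(keep.sum())
        if sample.error_rate > 0:
            n_err = rng.binomial(L, sample.error_rate, size=n)
        else:
            n_err = np.zeros(n, dtype=int)
        for i in range(n):
            r = int(starts[i])
            seq = src.sequence[r : r + L]
            if n_err[i]:
                buf = bytearray(seq.encode())
                pos = rng.choice(L, size=int(n_err[i]), replace=False)
                for p in pos:
                    old = buf[p]
                    choices = [b for b in b"ACGT" if b != old]
                    buf[p] = choices[int(rng.integers(0, len(choices)))]
                seq = buf.decode()
            li = int(hit_ref[i])
            reads.append(
                ReadRecord(
                    read_id=f"{truth.sample_id}|r{read_no:07d}",
                    sequence=seq,
                    source_id=src.source_id,
                    hit_locus=src.loci[li][0] if li >= 0 else "",
                    annotated=bool(ann[i]),
                )
            )
            read_no += 1
    counts = _count_frame(truth, standards, truth.sample_id, latent, annotated)
    return reads, counts


def simulate_counts(
    truth: CommunityTruth,
    standards: list[StandardSpec],
    sample: SampleSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a TrueCounts table directly from the multinomial read model.

    Distributionally identical to counting the output of
    ``simulate_reads`` but without materializing sequences; used for
    replicated estimator experiments.
    """
    sources = _sources(truth, standards, sample)
    weights = np.array([s.copies * s.genome_length for s in sources], dtype=float)
    total_mass = weights.sum()
    if total_mass <= 0:
        raise ValueError("total DNA mass must be > 0")
    L = sample.read_length
    _check_read_length(sources, L)
    if rng is None:
        rng = np.random.default_rng(sample.seed)

    cats: list[tuple[str, float]] = []  # (aggregate key or "", probability)
    probs: list[float] = []
    sens_by_cat: list[float] = []
    for src, w in zip(sources, weights):
        p_src = w / total_mass
        n_starts = src.genome_length - L + 1
        covered = 0
        for ref_id, ref_class, s0, e0, sens in src.loci:
            n_pos = n_hit_starts(s0, e0, src.genome_length, L)
            covered += n_pos
            agg = ref_id if ref_class != STANDARD_CLASS else src.source_id
            cats.append((agg, sens))
            probs.append(p_src * n_pos / n_starts)
        cats.append(("", 1.0))
        probs.append(p_src * (n_starts - covered) / n_starts)
    draws = rng.multinomial(sample.n_reads, np.array(probs))
    latent: dict[str, int] = {}
    annotated: dict[str, int] = {}
    for (agg, sens), k in zip(cats, draws):
        if not agg:
            continue
        latent[agg] = latent.get(agg, 0) + int(k)
        kept = int(rng.binomial(k, sens)) if sens < 1.0 else int(k)
        annotated[agg] = annotated.get(agg, 0) + kept
    return _count_frame(truth, standards, truth.sample_id, latent, annotated)


def expected_counts(
    truth: CommunityTruth,
    standards: list[StandardSpec],
    sample: SampleSpec,
) -> pd.DataFrame:
    """Closed-form expected latent and annotated hit counts per aggregate."""
    sources = _sources(truth, standards, sample)
    weights = np.array([s.copies * s.genome_length for s in sources], dtype=float)
    total_mass = weights.sum()
    L = sample.read_length
    latent: dict[str, float] = {}
    annotated: dict[str, float] = {}
    for src, w in zip(sources, weights):
        p_src = w / total_mass
        n_starts = src.genome_length - L + 1
        for ref_id, ref_class, s0, e0, sens in src.loci:
            n_pos = n_hit_starts(s0, e0, src.genome_length, L)
            agg = ref_id if ref_class != STANDARD_CLASS else src.source_id
            mu = sample.n_reads * p_src * n_pos / n_starts
            latent[agg] = latent.get(agg, 0.0) + mu
            annotated[agg] = annotated.get(agg, 0.0) + mu * sens
    return _count_frame(truth, standards, truth.sample_id, latent, annotated, value_dtype=float)
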