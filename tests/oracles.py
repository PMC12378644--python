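"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — brute
force, enumeration, or single closed-form expressions — and must not
import implementation internals beyond plain data containers.
"""

from __future__ import annotations

import numpy as np


def brute_force_best_hit(read: str, references, thresholds_by_class):
    """Exhaustive all-offsets ungapped best hit.

    ``references`` yields objects with ref_id / ref_class / sequence.
    Scores every (reference, offset) pair; a hit is accepted iff
    identity >= class min (and confirm threshold, if any) and the
    aligned span >= class fraction x read length. Best = max identity,
    then max span, then smallest ref_id. Returns (ref_id, ref_class,
    identity, span) or None.
    """
    L = len(read)
    xr = np.frombuffer(read.encode(), dtype=np.uint8)
    best = None
    for ref in references:
        th = thresholds_by_class.get(ref.ref_class)
        if th is None:
            continue
        xf = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        for offset in range(-(L - 1), len(xf)):
            # read position i aligns with reference position offset + i
            lo = max(0, -offset)
            hi = min(L, len(xf) - offset)
            span = hi - lo
            if span <= 0 or span < th.min_aln_read_fraction * L:
                continue
            matches = int(np.count_nonzero(xr[lo:hi] == xf[lo + offset : hi + offset]))
            identity = 100.0 * matches / span
            if identity < th.min_pct_identity:
                continue
            confirm = getattr(th, "confirm_pct_identity", None)
            if confirm is not None and identity < confirm:
                continue
            cand = (ref.ref_id, ref.ref_class, identity, span)
            if best is None:
                best = cand
                continue
            b_id, _, b_ident, b_span = best
            if (identity, span) > (b_ident, b_span):
                best = cand
            elif (identity, span) == (b_ident, b_span) and ref.ref_id < b_id:
                best = cand
    return best


def enumerate_hit_starts(start: int, end: int, genome_length: int, read_length: int) -> int:
    """Count read start positions overlapping [start, end) by >= half a read."""
    n = 0
    for r in range(genome_length - read_length + 1):
        overlap = min(end, r + read_length) - max(start, r)
        if overlap > 0 and 2 * overlap >= read_length:
            n += 1
    return n


def expected_annotated_hits(
    n_reads: int,
    copies: float,
    genome_length: int,
    locus_start: int,
    locus_end: int,
    total_mass: float,
    read_length: int,
    sensitivity: float,
) -> float:
    """Closed-form expected annotated hits for one locus of one source."""
    n_pos = enumerate_hit_starts(locus_start, locus_end, genome_length, read_length)
    p_source = copies * genome_length / total_mass
    return n_reads * p_source * n_pos / (genome_length - read_length + 1) * sensitivity


# ---------------------------------------------------------------------------
# regression / ordination oracles


def slope_through_origin(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float((x * y).sum() / (x * x).sum())


def slope_ols(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    return float(((x - mx) * (y - my)).sum() / ((x - mx) ** 2).sum())


def slope_sma(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    r = pearson_r(x, y)
    return float(np.sign(r) * y.std(ddof=1) / x.std(ddof=1))


def pearson_r(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def braycurtis_pair(u, v) -> float:
    u, v = np.asarray(u, float), np.asarray(v, float)
    return float(np.abs(u - v).sum() / (u + v).sum())


def braycurtis_all_pairs(matrix) -> np.ndarray:
    m = np.asarray(matrix, float)
    n = m.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = braycurtis_pair(m[i], m[j])
    return d


def pcoa_variance_2axes(d: np.ndarray) -> float:
    """Variance on axes 1-2 via the elementwise Gower double-centering.

    b_ij = -1/2 (d_ij^2 - rowmean_i - colmean_j + grandmean); clip
    negative eigenvalues at zero.
    """
    d = np.asarray(d, float)
    n = d.shape[0]
    d2 = d**2
    row = d2.mean(axis=1)
    grand = d2.mean()
    b = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            b[i, j] = -0.5 * (d2[i, j] - row[i] - row[j] + grand)
    eig = np.sort(np.linalg.eigvalsh(b))[::-1]
    pos = np.clip(eig, 0, None)
    return float(pos[:2].sum() / pos.sum())
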