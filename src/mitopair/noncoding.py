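"""Structural decomposition of non-coding regions.

Palindromic stem-loop (hairpin) detection, tandem-repeat discovery by
seed-and-extend self-comparison, Hamming motif scanning, and repeat-unit
p-distance matrices.  Detection is purely complementarity-based: a hairpin
is an inverted repeat whose arms pair under the declared rule (Watson-Crick,
optionally wobble G-U), with no thermodynamic scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import infer_unassigned_regions
from .divergence import AlignedPair, p_distance
from .genomes import FeatureTable, GenomeRecord, extract_region

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def _pairs(allow_gu: bool) -> set:
    return _WC | _GU if allow_gu else set(_WC)


@dataclass(frozen=True)
class HairpinStructure:
    """A stem-loop: 1-based start of the 5' arm, stem and loop lengths."""

    start: int
    stem_len: int
    loop_len: int
    arm5: str
    arm3: str
    loop: str
    pairing: str  # "WC" or "WC+GU"
    mismatches: int = 0

    @property
    def span(self) -> int:
        return 2 * self.stem_len + self.loop_len

    @property
    def stop(self) -> int:
        return self.start + self.span - 1


def find_hairpins(
    seq: str,
    min_stem: int = 5,
    loop_range: tuple[int, int] = (3, 30),
    allow_gu: bool = False,
    max_arm_mismatch: int = 0,
) -> list[HairpinStructure]:
    """All maximal hairpins in ``seq`` meeting the thresholds, by position.

    Maximality: the stem cannot be extended outward by one further base pair
    while remaining a valid stem (same loop, mismatch budget included).
    Coordinates are 1-based within ``seq``.
    """
    if min_stem < 2:
        raise ValueError("min_stem must be >= 2")
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n = len(seq)
    pairs = _pairs(allow_gu)
    lo, hi = loop_range
    found: list[HairpinStructure] = []
    for loop in range(lo, hi + 1):
        # grow the stem outward around every possible loop placement
        for loop_start in range(1, n - loop):  # need >=1 nt each side
            k = 0
            mism = 0
            while True:
                i = loop_start - k - 1
                j = loop_start + loop + k
                if i < 0 or j >= n:
                    break
                if (seq[i], seq[j]) in pairs:
                    k += 1
                    continue
                # a mismatch may sit inside the stem but not at its ends;
                # accept it only if a further true pair follows
                if (
                    mism < max_arm_mismatch
                    and k >= 1
                    and i - 1 >= 0
                    and j + 1 < n
                    and (seq[i - 1], seq[j + 1]) in pairs
                ):
                    mism += 1
                    k += 1
                    continue
                break
            if k >= min_stem:
                s = loop_start - k
                found.append(
                    HairpinStructure(
                        start=s + 1,
                        stem_len=k,
                        loop_len=loop,
                        arm5=seq[s:s + k],
                        arm3=seq[s + k + loop:s + 2 * k + loop],
                        loop=seq[s + k:s + k + loop],
                        pairing="WC+GU" if allow_gu else "WC",
                        mismatches=mism,
                    )
                )
    return sorted(set(found), key=lambda h: (h.start, h.loop_len))


def scan_gene_upstream_hairpins(
    genome: GenomeRecord,
    ft: FeatureTable,
    window: int = 60,
    min_stem: int = 5,
    loop_range: tuple[int, int] = (3, 30),
    allow_gu: bool = False,
) -> dict:
    """Hairpins in the non-coding sequence upstream of qualifying protein genes.

    A gene qualifies when its nearest upstream gene-like feature in circular
    order is not a tRNA and non-coding sequence actually precedes the start:
    small unassigned regions are skipped while walking upstream, the LUR acts
    as a (non-tRNA) breaker, and a gene directly abutting another gene or an
    rRNA has nothing to scan.  The scan covers the intervening non-coding
    stretch up to ``window`` nt before the start codon, extended 20 nt into
    the gene so structures containing the initiation codon are caught.
    Returns gene -> list of (hairpin, genome start, contains_start); the flag
    is set when the hairpin span covers the start codon.
    """
    elements = sorted(ft.of_type("CDS", "tRNA", "rRNA", "LUR"),
                      key=lambda f: (f.start, -f.stop))
    if not any(f.ftype == "LUR" for f in elements):
        inferred = infer_unassigned_regions(ft)
        from .annotation import unassigned_to_features

        elements += [
            f for f in unassigned_to_features(inferred, ft.genome_length)
            if f.ftype == "LUR"
        ]
        elements.sort(key=lambda f: (f.start, -f.stop))
    n = genome.length
    results = {}
    for idx, f in enumerate(elements):
        if f.ftype != "CDS":
            continue
        prev = elements[idx - 1]  # circular: idx 0 wraps to the last element
        if prev.ftype == "tRNA":
            continue
        start_u = f.start + (n if idx == 0 else 0)  # unwrapped coordinate
        if prev.ftype == "LUR":
            bound = prev.start  # the scan may reach into the LUR tail
        else:
            bound = prev.stop + 1
            if start_u - prev.stop - 1 <= 0:
                continue  # abuts a gene/rRNA: no non-coding sequence to scan
        lo = max(bound, start_u - window)
        hi = min(start_u + 20, f.stop + (n if idx == 0 else 0))
        if lo > n:  # whole scan window sits past the origin
            lo, hi, start_u = lo - n, hi - n, start_u - n
        region = extract_region(genome, lo, hi, circular_wrap=True)
        hairpins = find_hairpins(region, min_stem, loop_range, allow_gu)
        annotated = []
        for h in hairpins:
            g_start = (lo + h.start - 2) % n + 1
            h_lo = lo + h.start - 1
            contains_start = h_lo <= start_u and start_u + 2 <= h_lo + h.span - 1
            annotated.append((h, g_start, contains_start))
        results[f.name] = annotated
    return results


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatUnit:
    index: int
    start: int  # 1-based within the region
    stop: int
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class RepeatDecomposition:
    region_label: str
    units: list
    consensus_length: int
    pd_matrix: np.ndarray | None = None  # between full-length units
    se_matrix: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return len(self.units)


def find_tandem_repeats(
    seq: str,
    min_unit: int = 50,
    max_divergence: float = 0.05,
    k: int = 13,
    min_tail: int = 10,
    label: str = "",
    B: int = 1000,
    seed: int = 0,
) -> RepeatDecomposition:
    """Largest tandem-repeat array in ``seq`` by seed-and-extend self-comparison.

    Exact ``k``-mer seeds propose candidate periods d >= min_unit; each seed
    is extended ungapped comparing position x with x + d while the running
    mismatch fraction stays within ``max_divergence``.  The winning array
    maximizes the spanned length, with two qualifications: a shorter period
    is preferred whenever it spans within 25 nt of the maximum (an array of n
    units matches its own first harmonic at period 2d over the same span, and
    the fundamental period must win), and remaining span ties go to the
    leftmost start.  Because the running-ratio rule accumulates slack over a
    long low-divergence array, the raw extension ends can wander into random
    flanking sequence; both boundaries are therefore refined by a
    change-point criterion that maximizes the match-density contrast between
    the 30 nt inside and outside the boundary.  The refined span is cut into
    full units of length d plus a trailing partial unit (>= min_tail nt)
    flagged as truncated.  The pairwise p-distance matrix covers full-length
    units.  An empty decomposition is a valid result.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_unit:
        return RepeatDecomposition(label, [], 0)

    kmers: dict = {}
    periods: set = set()
    for i in range(n - k + 1):
        km = seq[i:i + k]
        if km in kmers:
            for j in kmers[km]:
                d = i - j
                if d >= min_unit:
                    periods.add(d)
            kmers[km].append(i)
        else:
            kmers[km] = [i]

    def match_track(d: int) -> np.ndarray:
        m = n - d
        return np.frombuffer(seq[:m].encode(), dtype=np.uint8) == np.frombuffer(
            seq[d:].encode(), dtype=np.uint8
        )

    candidates: list[tuple[int, int, int, int]] = []  # (span, start, eq_end, d)
    for d in sorted(periods):
        eq = match_track(d)
        m = eq.size
        # greedy segments: maximal stretches with mismatch ratio within budget
        x = 0
        while x < m:
            if not eq[x]:
                x += 1
                continue
            mism = 0
            last_good = x
            y = x
            while y < m:
                if not eq[y]:
                    if (mism + 1) / (y - x + 1) > max_divergence:
                        break
                    mism += 1
                else:
                    last_good = y
                y += 1
            end = last_good
            if end - x + 1 >= min_unit:  # at least one full period matched
                candidates.append((end - x + 1 + d, x, end, d))
            x = max(y + 1, x + 1)
    if not candidates:
        return RepeatDecomposition(label, [], 0)

    smax = max(c[0] for c in candidates)
    span, x0, eq_end, d = min(
        (c for c in candidates if c[0] >= smax - 25),
        key=lambda c: (c[3], c[1]),
    )
    eq = match_track(d)

    # log-likelihood contribution of each track position under the two
    # regimes: inside the array matches occur at ~(1 - divergence), in a
    # random flank at ~1/4.  Scoring boundaries this way makes an excursion
    # past accidental flank matches expensive (a flank match gains ~1.3 but
    # the accompanying flank mismatches cost ~3.6 each).
    _p_in, _p_out = 0.95, 0.25
    c_in = np.where(eq, np.log(_p_in), np.log(1 - _p_in))
    c_out = np.where(eq, np.log(_p_out), np.log(1 - _p_out))

    # expected per-base contributions, used to pad windows clipped at the
    # sequence edges so that clipping does not bias the comparison
    _e_in = _p_in * np.log(_p_in) + (1 - _p_in) * np.log(1 - _p_in)
    _e_out = _p_out * np.log(_p_out) + (1 - _p_out) * np.log(1 - _p_out)

    def refine(lo_b: int, hi_b: int, left: bool, w: int = 30) -> int:
        """Maximum-likelihood change point over [lo_b, hi_b].  The raw
        extension end can overrun arbitrarily far into a flank (the
        running-ratio budget grows with the array), so the search covers the
        whole raw segment rather than a fixed neighbourhood."""
        m = eq.size
        best_b, best_score = None, None
        for b in range(max(0, lo_b), min(m - 1, hi_b) + 1):
            if left:
                ins = c_in[b:min(m, b + w)]
                out = c_out[max(0, b - w):b]
            else:
                ins = c_in[max(0, b - w + 1):b + 1]
                out = c_out[b + 1:min(m, b + 1 + w)]
            score = (
                ins.sum() + (w - ins.size) * _e_in
                + out.sum() + (w - out.size) * _e_out
            )
            if best_score is None or score > best_score or (
                score == best_score and (b < best_b if left else b > best_b)
            ):
                best_b, best_score = b, score
        return best_b

    lo = refine(x0 - 30, x0 + (eq_end - x0) // 2, left=True)
    hi = refine(x0 + (eq_end - x0) // 2, eq_end + 30, left=False) + d
    total = hi - lo + 1
    if total < 2 * min_unit:
        return RepeatDecomposition(label, [], 0)
    n_full = total // d
    rem = total % d
    units = [
        RepeatUnit(i + 1, lo + i * d + 1, lo + (i + 1) * d)
        for i in range(n_full)
    ]
    if rem >= min_tail:
        units.append(
            RepeatUnit(n_full + 1, lo + n_full * d + 1, lo + total, truncated=True)
        )
    full_seqs = [seq[u.start - 1:u.stop] for u in units if not u.truncated]
    pd_m = se_m = None
    if len(full_seqs) >= 2:
        pd_m, se_m = unit_distance_matrix(full_seqs, B=B, seed=seed)
    return RepeatDecomposition(label, units, d, pd_m, se_m)


def unit_distance_matrix(
    units: Sequence[str], B: int = 1000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise p-distances (with bootstrap SEs) between repeat units.

    Units must be pre-aligned: equal-length slices or an external alignment.
    Returns (pD matrix, SE matrix), symmetric with zero diagonals.
    """
    if len(units) < 2:
        raise ValueError("need at least two units")
    lengths = {len(u) for u in units}
    if len(lengths) != 1:
        raise ValueError(
            f"unit lengths differ ({sorted(lengths)}); align them first"
        )
    m = len(units)
    pd_m = np.zeros((m, m))
    se_m = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            est = p_distance(AlignedPair(units[i], units[j]), B=B, seed=seed)
            pd_m[i, j] = pd_m[j, i] = est.pD
            se_m[i, j] = se_m[j, i] = est.SE
    return pd_m, se_m


def motif_scan(seq: str, motif: str, max_mismatch: int = 0) -> list[tuple[int, int]]:
    """All 1-based positions where ``motif`` occurs within ``max_mismatch``
    Hamming distance; overlapping hits allowed.  Returns (position, mismatches)."""
    seq, motif = seq.upper(), motif.upper()
    L = len(motif)
    if L > len(seq):
        raise ValueError("motif longer than sequence")
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    n_win = len(seq) - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(s, L)
    mism = (windows != m).sum(axis=1)
    return [(int(i) + 1, int(mm)) for i, mm in enumerate(mism) if mm <= max_mismatch]
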