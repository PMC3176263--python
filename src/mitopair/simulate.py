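"""Synthetic paired F/M mitochondrial genomes with recorded ground truth.

The generator emulates the statistical structure of a doubly-uniparental-
inheritance genome pair: shared gene order, AT-rich composition with the
H-strand skews of the real molecules, deep synonymous / shallow
nonsynonymous coding divergence, a large unassigned region (LUR) built from
a tandem-repeat array with planted palindromic hairpins, a duplicated gene
in the male genome, and one gene ending in an incomplete (polyadenylation-
completed) stop codon.

Divergence is planted on the estimator's own scale: per-gene (Ks, Ka)
targets are Jukes-Cantor-inverted to per-site difference proportions, and
single-base codon changes classified through the genetic code are accepted
until the realized synonymous/nonsynonymous difference counts reach those
proportions of the gene's potential site counts.  Each mutated codon is then
assigned to exactly one lineage, so both lineages carry about half the
changes while the pairwise difference set equals the planted set exactly
(same-site collisions between independently evolving lineages would
otherwise bias pairwise divergence below target at deep Ks).  Recovery tests
are therefore calibration tests: the estimator still has to count sites and
average pathways on raw sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .divergence import jc_invert
from .genomes import (
    Feature,
    FeatureTable,
    GeneticCode,
    GenomeRecord,
    INVERTEBRATE_MITO,
    reverse_complement,
)
from . import fixtures

_BASE_ORDER = "TCAG"

#: Coding-strand composition target (%T, %C, %A, %G) of the real genomes.
DEFAULT_COMPOSITION = (39.3, 12.0, 27.2, 21.4)

#: Whole-proteome divergence regime of the real pair.
DEFAULT_KS = 0.716
DEFAULT_KA = 0.143


@dataclass
class HairpinSpec:
    stem: int = 8
    loop: int = 5
    count: int = 2


@dataclass
class LurSpec:
    """Tandem-repeat array + hairpin layout of the synthetic control region."""

    unit_length: int = 540
    unit_count: int = 2
    unit_divergence: float = 0.004  # substitutions/site between repeat copies
    truncated_length: int = 17  # 0 disables the truncated trailing unit
    spacer_length: int = 60
    hairpins: HairpinSpec = field(default_factory=HairpinSpec)


@dataclass
class DuplicationSpec:
    gene: str = "cox2"
    copy_name: str = "cox2b"
    extension_nt: int = 123  # in-frame extension of the duplicated copy
    ks: float = DEFAULT_KS
    ka: float = DEFAULT_KA


@dataclass
class SimulationConfig:
    seed: int
    scale: int = 4  # template lengths divided by this (1 = full size)
    composition: tuple = DEFAULT_COMPOSITION
    divergence: dict = field(default_factory=dict)  # gene -> (Ks, Ka) overrides
    default_ks: float = DEFAULT_KS
    default_ka: float = DEFAULT_KA
    lur_spec: LurSpec = field(default_factory=LurSpec)
    duplication: DuplicationSpec | None = field(default_factory=DuplicationSpec)
    incomplete_stop_gene: str | None = "nad5"
    R: float = 2.0  # ts/tv ratio used for the planted site counts

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 100.0) > 0.5:
            raise ValueError("composition must sum to 100")
        for g, (ks, ka) in self.divergence.items():
            if not (0 <= jc_invert(ks) < 0.75 and 0 <= jc_invert(ka) < 0.75):
                raise ValueError(f"{g}: divergence target saturates the JC scale")

    def targets(self, gene: str) -> tuple[float, float]:
        return self.divergence.get(gene, (self.default_ks, self.default_ka))


@dataclass
class PlantedGene:
    ks_target: float
    ka_target: float
    S: float
    N: float
    Sd: float  # pathway-averaged realized differences
    Nd: float
    n_codons: int


@dataclass
class PlantedLur:
    lineage: str
    start: int  # absolute 1-based genome coordinates
    stop: int
    unit_starts: list
    unit_stops: list
    unit_truncated: list
    unit_divergences: list  # realized fraction vs the first unit
    hairpin_starts: list  # absolute start of each planted stem-loop
    hairpin_stems: list
    hairpin_loops: list


@dataclass
class GroundTruth:
    """Everything needed to score every estimator in the package."""

    seed: int
    alignments: dict  # gene -> (F coding seq, M coding seq), true alignment
    planted_genes: dict  # gene -> PlantedGene
    lur: dict  # lineage -> PlantedLur
    duplication: dict | None

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return asdict(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=enc, indent=1)


# ---------------------------------------------------------------------------
# composition-constrained codon sampling
# ---------------------------------------------------------------------------

def _codon_distribution(
    composition: tuple, code: GeneticCode, iters: int = 60
) -> tuple[list, np.ndarray]:
    """Distribution over sense codons whose per-position base marginals match
    the target composition (iterative proportional fitting)."""
    target = np.array(composition, dtype=float) / 100.0
    sense = sorted(code.sense_codons)
    base_idx = {b: i for i, b in enumerate(_BASE_ORDER)}
    probs = np.array(
        [np.prod([target[base_idx[b]] for b in c]) for c in sense]
    )
    probs /= probs.sum()
    for _ in range(iters):
        for pos in range(3):
            marg = np.zeros(4)
            for i, c in enumerate(sense):
                marg[base_idx[c[pos]]] += probs[i]
            scale = np.where(marg > 0, target / np.maximum(marg, 1e-300), 0.0)
            for i, c in enumerate(sense):
                probs[i] *= scale[base_idx[c[pos]]]
            probs /= probs.sum()
    return sense, probs


def random_dna(rng: np.random.Generator, length: int, composition: tuple) -> str:
    p = np.array(composition, dtype=float) / 100.0
    return "".join(rng.choice(list(_BASE_ORDER), size=length, p=p / p.sum()))


def _random_codons(
    rng: np.random.Generator, n: int, sense: list, probs: np.ndarray
) -> list:
    return list(rng.choice(sense, size=n, p=probs))


# ---------------------------------------------------------------------------
# codon-level mutation planting
# ---------------------------------------------------------------------------

@dataclass
class MutationRecord:
    codon_index: int
    position: int  # 0..2 within the codon
    old: str
    new: str
    synonymous: bool


def mutate_codons(
    seq: str,
    ks_target: float,
    ka_target: float,
    code: GeneticCode = INVERTEBRATE_MITO,
    seed: int | np.random.Generator = 0,
    R: float = 2.0,
    mutable: slice | None = None,
    proposal: tuple | None = None,
) -> tuple[str, dict]:
    """Plant synonymous/nonsynonymous changes onto an in-frame sequence.

    Proposes single-base codon changes (at most one hit per site; the
    replacement base is drawn from ``proposal`` — %T,%C,%A,%G weights, so a
    composition bias propagates through the mutation process — or uniformly
    when ``proposal`` is None).  Each accepted change must move the
    pathway-averaged synonymous/nonsynonymous difference counts between the
    original and the evolving sequence toward round-trip targets p_s * S and
    p_n * N, where p_s/p_n are the Jukes-Cantor inversions of the targets
    and S/N the modified Nei-Gojobori potential site counts of the input at
    ratio ``R``.  Counting realized divergence with the method's own
    pathway averaging is what makes the targets live on the estimator's
    scale; the estimator applied to the output still has to redo site
    counting and pathway averaging from raw sequence.  Changes creating stop
    codons — or codon pairs whose every pathway crosses a stop — are never
    accepted.  ``mutable`` restricts the codon range (used to protect start
    and stop codons).

    Returns (mutated sequence, info) where info carries realized counts and
    the per-mutation records.
    """
    # site weights and pathway averaging shared with the estimator's definition
    from .divergence import _cached_diffs, _cached_sites

    if len(seq) % 3:
        raise ValueError("sequence length is not a codon multiple")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    original = list(codons)
    if any(code.is_stop(c) for c in codons[:-1]):
        raise ValueError("internal stop codon in input")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = (mutable.start or 0, mutable.stop or len(codons)) if mutable else (0, len(codons))
    idx_pool = [i for i in range(lo, hi) if not code.is_stop(codons[i])]
    if not idx_pool:
        raise ValueError("no mutable codons")

    S = N = 0.0
    for i in idx_pool:
        s, n = _cached_sites(codons[i], code.code_id, R)
        S += s
        N += n
    ps, pn = jc_invert(ks_target), jc_invert(ka_target)
    sd_target, nd_target = ps * S, pn * N

    # pathway-averaged (sd, nd) of each codon against its original state
    per_codon = {i: (0.0, 0.0) for i in idx_pool}
    hit: set = set()
    mutations: list[MutationRecord] = []
    sd = nd = 0.0
    tol = 0.51  # pathway averages move in halves/thirds; stop within half a change
    bases = list(_BASE_ORDER)
    if proposal is None:
        weights = np.full(4, 0.25)
    else:
        weights = np.array(proposal, dtype=float)
        weights /= weights.sum()
    budget = 4000 * max(1, len(idx_pool)) * 3
    proposals = 0
    while (sd < sd_target - tol or nd < nd_target - tol) and proposals < budget:
        proposals += 1
        ci = idx_pool[int(rng.integers(len(idx_pool)))]
        pos = int(rng.integers(3))
        if (ci, pos) in hit:
            continue
        cur = codons[ci]
        new_base = bases[int(rng.choice(4, p=weights))]
        if new_base == cur[pos]:
            continue
        mutant = cur[:pos] + new_base + cur[pos + 1:]
        if code.is_stop(mutant):
            continue
        diffs = _cached_diffs(original[ci], mutant, code.code_id)
        if diffs is None:  # the estimator would have to drop this codon
            continue
        old_sd, old_nd = per_codon[ci]
        new_sd = sd - old_sd + diffs[0]
        new_nd = nd - old_nd + diffs[1]
        if new_sd > sd_target + tol or new_nd > nd_target + tol:
            continue
        if new_sd + new_nd <= sd + nd:  # must add net divergence
            continue
        mutations.append(
            MutationRecord(
                ci, pos, cur[pos], new_base,
                synonymous=code.translate(mutant) == code.translate(cur),
            )
        )
        codons[ci] = mutant
        per_codon[ci] = diffs
        hit.add((ci, pos))
        sd, nd = new_sd, new_nd
    if sd < sd_target - tol or nd < nd_target - tol:
        raise ValueError(
            f"divergence target unreachable (saturation): "
            f"planted {sd:.1f}/{sd_target:.1f} synonymous, "
            f"{nd:.1f}/{nd_target:.1f} nonsynonymous"
        )
    info = {
        "S": S,
        "N": N,
        "Sd": sd,
        "Nd": nd,
        "sd_target": sd_target,
        "nd_target": nd_target,
        "mutations": mutations,
    }
    return "".join(codons), info


# ---------------------------------------------------------------------------
# LUR assembly
# ---------------------------------------------------------------------------

def _assemble_lur(
    rng: np.random.Generator, spec: LurSpec, composition: tuple
) -> tuple[str, dict]:
    """Build spacer + tandem array + truncated unit + hairpin-bearing tail.

    Returns (sequence, truth) with 1-based coordinates relative to the LUR.
    """
    unit0 = random_dna(rng, spec.unit_length, composition)
    parts = [random_dna(rng, spec.spacer_length, composition)]
    pos = spec.spacer_length
    unit_starts, unit_stops, unit_trunc, unit_div = [], [], [], []
    for i in range(spec.unit_count):
        if i == 0:
            unit = unit0
            realized = 0.0
        else:
            u = list(unit0)
            n_mut = rng.binomial(spec.unit_length, spec.unit_divergence)
            sites = rng.choice(spec.unit_length, size=n_mut, replace=False)
            for s in sites:
                u[s] = rng.choice([b for b in "ACGT" if b != u[s]])
            unit = "".join(u)
            realized = n_mut / spec.unit_length
        parts.append(unit)
        unit_starts.append(pos + 1)
        unit_stops.append(pos + len(unit))
        unit_trunc.append(False)
        unit_div.append(realized)
        pos += len(unit)
    if spec.truncated_length:
        tail = unit0[: spec.truncated_length]
        parts.append(tail)
        unit_starts.append(pos + 1)
        unit_stops.append(pos + len(tail))
        unit_trunc.append(True)
        unit_div.append(0.0)
        pos += len(tail)
    hp_starts, hp_stems, hp_loops = [], [], []
    for _ in range(spec.hairpins.count):
        gap = random_dna(rng, 8, composition)
        stem = random_dna(rng, spec.hairpins.stem, composition)
        loop = random_dna(rng, spec.hairpins.loop, composition)
        hairpin = stem + loop + reverse_complement(stem)
        parts.append(gap)
        pos += len(gap)
        parts.append(hairpin)
        hp_starts.append(pos + 1)
        hp_stems.append(spec.hairpins.stem)
        hp_loops.append(spec.hairpins.loop)
        pos += len(hairpin)
    parts.append(random_dna(rng, spec.spacer_length, composition))
    pos += spec.spacer_length
    truth = {
        "unit_starts": unit_starts,
        "unit_stops": unit_stops,
        "unit_truncated": unit_trunc,
        "unit_divergences": unit_div,
        "hairpin_starts": hp_starts,
        "hairpin_stems": hp_stems,
        "hairpin_loops": hp_loops,
    }
    return "".join(parts), truth


# ---------------------------------------------------------------------------
# genome template and pair simulation
# ---------------------------------------------------------------------------

def _template(scale: int, incomplete_stop_gene: str | None) -> list:
    """(ftype, name, length, anticodon) skeleton scaled from the published
    F-genome organization; tRNA lengths are kept at full size."""
    rows = []
    for f in fixtures.feature_table_f():
        if f.ftype == "CDS":
            n_codons = max(10, round(f.length / scale / 3))
            length = n_codons * 3
            if f.name == incomplete_stop_gene:
                length += 1
        elif f.ftype == "tRNA":
            length = f.length
        elif f.ftype == "rRNA":
            length = max(60, f.length // scale)
        elif f.ftype == "UR":
            length = max(2, f.length // scale)
        else:  # LUR placeholder; real length set by LurSpec at assembly
            length = 0
        rows.append((f.ftype, f.name, length, f.anticodon))
    return rows


def simulate_pair(config: SimulationConfig):
    """Simulate an (F, M) genome pair with recorded ground truth.

    Returns (genome_f, table_f, genome_m, table_m, truth).  Deterministic for
    a fixed seed: identical config gives byte-identical sequences.
    """
    rng = np.random.default_rng(config.seed)
    code = INVERTEBRATE_MITO
    sense, probs = _codon_distribution(config.composition, code)
    template = _template(config.scale, config.incomplete_stop_gene)

    start_codons = ("ATG", "ATA")
    stop_codons = ("TAA", "TAG")

    # --- per-gene ancestors and planted mutations -------------------------
    gene_seqs: dict = {}  # gene -> (F coding seq, M coding seq, tail)
    planted: dict = {}
    alignments: dict = {}
    for ftype, name, length, _ in template:
        if ftype != "CDS":
            continue
        incomplete = name == config.incomplete_stop_gene
        n_codons = length // 3
        body = _random_codons(rng, n_codons - 2, sense, probs)
        start = start_codons[int(rng.integers(2))]
        stop = "" if incomplete else stop_codons[int(rng.integers(2))]
        ancestor = start + "".join(body) + (stop or "".join(
            _random_codons(rng, 1, sense, probs)))
        if incomplete:
            # last codon stays sense; the T tail is the incomplete stop
            tail = "T"
        else:
            tail = ""
        ks, ka = config.targets(name)
        mutated, info = mutate_codons(
            ancestor, ks, ka, code, rng, config.R,
            mutable=slice(1, n_codons - 1), proposal=config.composition,
        )
        # split mutated codons between the lineages, whole codons at a time
        anc_codons = [ancestor[i:i + 3] for i in range(0, len(ancestor), 3)]
        mut_codons = [mutated[i:i + 3] for i in range(0, len(mutated), 3)]
        f_codons, m_codons = list(anc_codons), list(anc_codons)
        for ci in sorted({m.codon_index for m in info["mutations"]}):
            if rng.integers(2):
                f_codons[ci] = mut_codons[ci]
            else:
                m_codons[ci] = mut_codons[ci]
        seq_f, seq_m = "".join(f_codons), "".join(m_codons)
        gene_seqs[name] = (seq_f + tail, seq_m + tail, start, stop or "T--")
        planted[name] = PlantedGene(
            ks_target=ks, ka_target=ka, S=info["S"], N=info["N"],
            Sd=info["Sd"], Nd=info["Nd"], n_codons=n_codons,
        )
        alignments[name] = (seq_f, seq_m)

    # --- duplicated gene (male only) --------------------------------------
    dup = config.duplication
    dup_truth = None
    dup_seq = None
    if dup is not None:
        src_f, src_m, start, stop = gene_seqs[dup.gene]
        core = src_m[: len(src_m) - 3]  # strip the stop before extending
        mutated, info = mutate_codons(
            core, dup.ks, dup.ka, code, rng, config.R,
            mutable=slice(1, len(core) // 3), proposal=config.composition,
        )
        ext = "".join(_random_codons(rng, dup.extension_nt // 3, sense, probs))
        dup_seq = mutated + ext + stop_codons[int(rng.integers(2))]
        dup_truth = {
            "copy": dup.copy_name,
            "source": dup.gene,
            "extension_nt": dup.extension_nt,
            "planted": asdict(
                PlantedGene(dup.ks, dup.ka, info["S"], info["N"],
                            info["Sd"], info["Nd"], len(dup_seq) // 3)
            ),
        }

    # --- LUR assembly ------------------------------------------------------
    lur_f_seq, lur_f_truth = _assemble_lur(rng, config.lur_spec, config.composition)
    lur_m_seq, lur_m_truth = _assemble_lur(rng, config.lur_spec, config.composition)

    # --- genome assembly ---------------------------------------------------
    def build(lineage: str) -> tuple[GenomeRecord, FeatureTable, dict]:
        parts: list = []
        feats: list = []
        pos = 0
        lur_abs = None
        lur_truth = lur_f_truth if lineage == "F" else lur_m_truth
        lur_seq = lur_f_seq if lineage == "F" else lur_m_seq
        for ftype, name, length, anticodon in template:
            pieces = [(ftype, name, length, anticodon)]
            if (
                lineage == "M"
                and dup is not None
                and ftype == "CDS"
                and name == dup.gene
            ):
                pieces = [
                    ("CDS", dup.copy_name, len(dup_seq), None),
                    ("UR", "UR-dup", max(2, 41 // config.scale), None),
                    (ftype, name, length, anticodon),
                ]
            for ftype_i, name_i, length_i, anti_i in pieces:
                if ftype_i == "CDS":
                    if name_i == (dup.copy_name if dup else None):
                        seq = dup_seq
                        start_c, stop_c = seq[:3], seq[-3:]
                    else:
                        seq_f, seq_m, start_c, stop_c = gene_seqs[name_i]
                        seq = seq_f if lineage == "F" else seq_m
                elif ftype_i == "LUR":
                    seq = lur_seq
                    lur_abs = (pos + 1, pos + len(seq))
                else:
                    seq = random_dna(rng, length_i, config.composition)
                start = pos + 1
                pos += len(seq)
                parts.append(seq)
                kwargs = {}
                if ftype_i == "CDS":
                    kwargs = {"start_codon": start_c, "stop_codon": stop_c}
                elif ftype_i == "tRNA":
                    kwargs = {"anticodon": anti_i}
                feats.append(
                    Feature(ftype=ftype_i, name=name_i, start=start, stop=pos, **kwargs)
                )
        sequence = "".join(parts)
        genome = GenomeRecord(
            id=f"sim-{lineage}", length=len(sequence), sequence=sequence,
            lineage_type=lineage,
        )
        table = FeatureTable(genome.id, genome.length, feats)
        lur_planted = PlantedLur(
            lineage=lineage,
            start=lur_abs[0],
            stop=lur_abs[1],
            unit_starts=[lur_abs[0] - 1 + s for s in lur_truth["unit_starts"]],
            unit_stops=[lur_abs[0] - 1 + s for s in lur_truth["unit_stops"]],
            unit_truncated=lur_truth["unit_truncated"],
            unit_divergences=lur_truth["unit_divergences"],
            hairpin_starts=[lur_abs[0] - 1 + s for s in lur_truth["hairpin_starts"]],
            hairpin_stems=lur_truth["hairpin_stems"],
            hairpin_loops=lur_truth["hairpin_loops"],
        )
        return genome, table, lur_planted

    # NOTE: the two builds must not interleave rng draws; build F fully first
    genome_f, table_f, lur_planted_f = build("F")
    genome_m, table_m, lur_planted_m = build("M")

    truth = GroundTruth(
        seed=config.seed,
        alignments=alignments,
        planted_genes=planted,
        lur={"F": lur_planted_f, "M": lur_planted_m},
        duplication=dup_truth,
    )
    return genome_f, table_f, genome_m, table_m, truth


def write_simulation(
    config: SimulationConfig, outdir
) -> dict:
    """Run :func:`simulate_pair` and emit FASTA + feature TSV per genome plus
    the ground truth as JSON.  Returns the paths written."""
    from pathlib import Path

    from .genomes import write_fasta, write_feature_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_f, table_f, genome_m, table_m, truth = simulate_pair(config)
    paths = {}
    for tag, genome, table in (("F", genome_f, table_f), ("M", genome_m, table_m)):
        fasta = outdir / f"sim_{tag}.fasta"
        tsv = outdir / f"sim_{tag}_features.tsv"
        write_fasta(genome, fasta)
        write_feature_table(table, tsv)
        paths[f"fasta_{tag}"] = fasta
        paths[f"features_{tag}"] = tsv
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = truth_path
    return paths
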