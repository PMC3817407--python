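"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions the pipeline is meant to
analyse: promoter collections with a planted -35/spacer/-10 motif in
configurable-GC background, toy genomes whose sigma operons carry planted
promoters upstream of the operon head, crosstalk matrices with a strong
cognate signal, ~10-fold leakiness variation and multiplicative lognormal
noise (fluorescence is positive and summarised by geometric means, hence
lognormal), sequestration-switch transfer functions, and subgroup-by-genome
presence matrices with configurable co-occurrence structure.

Every generator is a pure function of (parameters, seed). Planted
mutations always substitute to a *different* base chosen uniformly, so the
per-position mismatch fraction versus the consensus equals the mutation
rate exactly, which keeps the planted information content analytically
predictable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import BASE_INDEX, decode, random_dna, revcomp, validate_dna
from .errors import ValidationError
from .roster_io import PromoterRecord

# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class MotifSpec:
    """Ground-truth bipartite motif for planting in synthetic promoters."""

    consensus35: str
    consensus10: str
    per_position_mutation_rate: float = 0.1
    spacer_distribution: Dict[int, float] = field(
        default_factory=lambda: {15: 0.2, 16: 0.6, 17: 0.2}
    )
    background_gc: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "consensus35", validate_dna(self.consensus35, context="consensus35"))
        object.__setattr__(self, "consensus10", validate_dna(self.consensus10, context="consensus10"))
        if not 0 <= self.per_position_mutation_rate < 0.5:
            raise ValidationError("mutation rate must be in [0, 0.5)")
        total = sum(self.spacer_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"spacer_distribution sums to {total}, not 1")
        if not 0 <= self.background_gc <= 1:
            raise ValidationError("background_gc must be in [0,1]")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth behind a simulated crosstalk screen."""

    cognate: Dict[str, str]  # sigma id -> promoter id
    cognate_fold: float
    offtarget_fold: Dict[Tuple[str, str], float] = field(default_factory=dict)
    leak: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.cognate_fold <= 1:
            raise ValidationError("cognate_fold must exceed 1")
        if any(v <= 0 for v in self.offtarget_fold.values()):
            raise ValidationError("off-target folds must be positive")
        if any(v <= 0 for v in self.leak.values()):
            raise ValidationError("leak values must be positive")

    def fold(self, sigma: str, promoter: str) -> float:
        if self.cognate.get(sigma) == promoter:
            return self.cognate_fold
        return self.offtarget_fold.get((sigma, promoter), 1.0)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise at the given coefficient of variation."""
    if cv < 0:
        raise ValidationError("noise_cv must be nonnegative")
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=size)


# ---------------------------------------------------------------------------
# Promoter collections


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Mutate each position independently; mutations always change the base."""
    out = []
    for b in seq:
        if rate > 0 and rng.random() < rate:
            choices = [c for c in "ACGT" if c != b]
            out.append(choices[rng.integers(3)])
        else:
            out.append(b)
    return "".join(out)


def _plant_window(
    rng: np.random.Generator, spec: MotifSpec, length: int, anchor10_end: int
) -> Tuple[str, int, int]:
    """Build one window with a planted motif; the -10 block's 3' end sits at
    ``anchor10_end`` (0-based, exclusive), mirroring real promoters where the
    -10 element is anchored near the transcription start site."""
    lengths = sorted(spec.spacer_distribution)
    probs = np.array([spec.spacer_distribution[k] for k in lengths])
    spacer = int(rng.choice(lengths, p=probs / probs.sum()))
    w35, w10 = len(spec.consensus35), len(spec.consensus10)
    start10 = anchor10_end - w10
    start35 = start10 - spacer - w35
    if start35 < 0 or anchor10_end > length:
        raise ValidationError(
            f"footprint (-35 {w35} + spacer {spacer} + -10 {w10}) does not fit the "
            f"{length} nt window"
        )
    bgseq = list(random_dna(rng, length, spec.background_gc))
    site35 = _mutate(rng, spec.consensus35, spec.per_position_mutation_rate)
    site10 = _mutate(rng, spec.consensus10, spec.per_position_mutation_rate)
    bgseq[start35 : start35 + w35] = site35
    bgseq[start10 : start10 + w10] = site10
    return "".join(bgseq), start35, start10


def gen_subgroup_promoters(
    spec: MotifSpec,
    n: int,
    seed: int,
    subgroup: int = 1,
    window: Tuple[int, int] = (-60, 20),
    uid_start: int = 1001,
) -> List[PromoterRecord]:
    """Generate n promoter windows with one planted bipartite motif each.

    The -10 element is anchored so its 3' end falls at promoter position -7;
    the spacer draw then sets where the -35 element lands. Same seed, same
    parameters -> byte-identical records.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    length = window[1] - window[0]
    anchor10_end = -7 - window[0]  # 0-based exclusive index of position -7
    records = []
    for i in range(n):
        seq, _, _ = _plant_window(rng, spec, length, anchor10_end)
        records.append(
            PromoterRecord(
                id=f"P_{subgroup:02d}_{uid_start + i}",
                sequence=seq,
                window=window,
                source="synthetic planted-motif generator",
            )
        )
    return records


def model_from_motif_spec(
    spec: MotifSpec,
    subgroup: int = 1,
    n_sites: int = 30,
    pseudocount: Optional[float] = None,
):
    """Ground-truth scoring model for a planted motif.

    Builds consensus-dominated PWMs plus the spec's spacer histogram, i.e.
    the model a perfect discovery run would learn. The default pseudocount
    (n_sites/3) spreads roughly the mutation-rate mass over off-consensus
    bases; a large pseudocount (e.g. 3*n_sites) yields a deliberately
    *relaxed*, low-information model — the signature of a promiscuous
    sigma whose binding specificity is weak.
    """
    from .motif_model import PromoterModel, SpacerModel, build_pwm

    pc = n_sites / 3 if pseudocount is None else pseudocount
    counts = {L: max(1, int(round(p * n_sites))) for L, p in spec.spacer_distribution.items()}
    return PromoterModel(
        subgroup=subgroup,
        pwm35=build_pwm([spec.consensus35] * n_sites, pseudocount=pc),
        pwm10=build_pwm([spec.consensus10] * n_sites, pseudocount=pc),
        spacer=SpacerModel(counts=counts, pseudocount=1.0),
    )


# ---------------------------------------------------------------------------
# Toy genomes


@dataclass(frozen=True)
class PlantedPromoter:
    sigma_gene_id: str
    operon_head_id: str
    strand: str
    promoter_seq: str  # gene-strand orientation
    genome_start: int  # 1-based inclusive, genome coordinates
    genome_end: int


@dataclass(frozen=True)
class ToyGenome:
    genome: str
    annotation: pd.DataFrame  # gene_id, start, end, strand, contig (1-based inclusive)
    planted: List[PlantedPromoter]


def gen_toy_genome(
    n_sigma_operons: int,
    intergenic_gap: int = 30,
    seed: int = 0,
    motif: Optional[MotifSpec] = None,
    gene_len: int = 600,
    two_gene_prob: float = 0.5,
    spacing: Tuple[int, int] = (150, 400),
    background_gc: float = 0.5,
    window_len: int = 80,
) -> ToyGenome:
    """Build a toy genome of sigma operons with planted upstream promoters.

    Each operon head is immediately preceded (in gene orientation) by a
    planted -60..+20 promoter window whose +1..+20 segment is the start of
    the head gene, so the window starts exactly 60 nt upstream of the gene
    start. With probability ``two_gene_prob`` the sigma gene is the
    *second* gene of its operon (separated from the head by
    ``intergenic_gap`` nt), so correct promoter recovery requires
    operon-aware upstream extraction. Strands are mixed.
    """
    if n_sigma_operons < 1:
        raise ValidationError("n_sigma_operons must be >= 1")
    if motif is None:
        motif = MotifSpec(consensus35="GGAACTT", consensus10="GTCTGA",
                          per_position_mutation_rate=0.05)
    rng = np.random.default_rng(seed)
    parts: List[str] = []
    rows: List[dict] = []
    planted: List[PlantedPromoter] = []
    cursor = 0  # 0-based length so far

    def emit(segment: str):
        nonlocal cursor
        parts.append(segment)
        cursor += len(segment)

    emit(random_dna(rng, int(rng.integers(*spacing)), background_gc))
    upstream_len = window_len - 20  # -60..-1 part of the window precedes the gene
    anchor10_end = upstream_len - 7  # -10 element ends at promoter position -7
    for k in range(n_sigma_operons):
        strand = "+" if rng.random() < 0.5 else "-"
        two = rng.random() < two_gene_prob
        prom, _, _ = _plant_window(rng, motif, window_len, anchor10_end)
        # the head gene starts at promoter position +1, i.e. cassette offset
        # upstream_len; its first 20 nt are the window's +1..+20 segment
        cassette = prom + random_dna(rng, gene_len - 20, background_gc)
        genes = [(f"op{k}_g1", upstream_len, upstream_len + gene_len)]
        if two:
            g2 = random_dna(rng, gene_len, background_gc)
            s2 = upstream_len + gene_len + intergenic_gap
            cassette += random_dna(rng, intergenic_gap, background_gc) + g2
            genes.append((f"sigma{k}", s2, s2 + gene_len))
            sigma_id, head_id = f"sigma{k}", f"op{k}_g1"
        else:
            genes[0] = (f"sigma{k}", upstream_len, upstream_len + gene_len)
            sigma_id = head_id = f"sigma{k}"
        M = len(cassette)
        g0 = cursor
        if strand == "+":
            emit(cassette)
            for gid, s, e in genes:
                rows.append({"gene_id": gid, "start": g0 + s + 1, "end": g0 + e,
                             "strand": "+", "contig": "toy"})
            planted.append(PlantedPromoter(sigma_id, head_id, "+", prom,
                                           g0 + 1, g0 + window_len))
        else:
            emit(revcomp(cassette))
            for gid, s, e in genes:
                rows.append({"gene_id": gid, "start": g0 + M - e + 1, "end": g0 + M - s,
                             "strand": "-", "contig": "toy"})
            planted.append(PlantedPromoter(sigma_id, head_id, "-", prom,
                                           g0 + M - window_len + 1, g0 + M))
        emit(random_dna(rng, int(rng.integers(*spacing)), background_gc))
    annotation = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand", "contig"])
    return ToyGenome(genome="".join(parts), annotation=annotation, planted=planted)


# ---------------------------------------------------------------------------
# Crosstalk matrices


def make_truth_table(
    n_clean: int,
    n_promiscuous: int = 0,
    cognate_fold: float = 100.0,
    promiscuous_fold_range: Tuple[float, float] = (5.0, 7.0),
    clean_targets_per_promiscuous: int = 4,
    clique_targets: int = 2,
    leak_span: float = 10.0,
    leak_floor: float = 10.0,
    seed: int = 0,
) -> TruthTable:
    """Design a ground-truth screen: ``n_clean`` orthogonal cognate pairs plus
    ``n_promiscuous`` pairs whose sigmas crosstalk broadly.

    Each promiscuous sigma activates other promiscuous promoters (a
    crosstalking clique of subgroups with similar motifs) and additionally
    a few clean promoters, assigned round-robin so the off-target burden
    any single clean pair suffers stays bounded. Promoter leakiness (basal
    fluorescence without any sigma) spans ``leak_span``-fold (default
    ~10-fold) on a log-uniform grid.
    """
    rng = np.random.default_rng(seed)
    n = n_clean + n_promiscuous
    sigmas = [f"ECF{(i % 43) + 1:02d}_{9000 + i}" for i in range(n)]
    promoters = [f"P_{(i % 43) + 1:02d}_{9000 + i}" for i in range(n)]
    cognate = dict(zip(sigmas, promoters))
    leak_vals = leak_floor * np.logspace(0, np.log10(leak_span), n)
    leak = dict(zip(promoters, rng.permutation(leak_vals)))
    offtarget: Dict[Tuple[str, str], float] = {}
    promiscuous = list(range(n_clean, n))
    clean_cursor = 0
    for idx, i in enumerate(promiscuous):
        partners = [j for j in promiscuous if j != i]
        for j in partners[:clique_targets]:
            offtarget[(sigmas[i], promoters[j])] = float(rng.uniform(*promiscuous_fold_range))
        if n_clean:
            for _ in range(clean_targets_per_promiscuous):
                j = clean_cursor % n_clean
                clean_cursor += 1
                offtarget[(sigmas[i], promoters[j])] = float(
                    rng.uniform(*promiscuous_fold_range)
                )
    return TruthTable(cognate=cognate, cognate_fold=cognate_fold,
                      offtarget_fold=offtarget, leak=leak)


def gen_crosstalk_matrix(truth: TruthTable, noise_cv: float, seed: int):
    """Simulate a measured fold-induction matrix from a TruthTable.

    cell(sigma, promoter) = true fold x mean-1 lognormal(cv). noise_cv=0
    returns the truth exactly; a fixed seed is fully reproducible.
    """
    from .crosstalk_analysis import CrosstalkMatrix  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    sigmas = list(truth.cognate)
    promoters = list(dict.fromkeys(truth.cognate.values()))
    base = np.array([[truth.fold(s, p) for p in promoters] for s in sigmas])
    noisy = base * _lognormal_factors(rng, noise_cv, base.shape)
    df = pd.DataFrame(noisy, index=sigmas, columns=promoters)
    return CrosstalkMatrix(data=df, kind="fold_induction")


@dataclass(frozen=True)
class ScreenStudy:
    """A full synthetic sigma x promoter screen: per-subgroup ground-truth
    motifs, scoring models (relaxed for the promiscuous clique), one
    promoter per subgroup and the cognate map."""

    specs: Dict[int, MotifSpec]
    models: Dict[int, object]  # subgroup -> PromoterModel
    promoters: Dict[int, PromoterRecord]
    sigma_ids: List[str]
    promoter_ids: List[str]
    cognate: Dict[str, str]
    clean_sigma_ids: List[str]


def make_screen_study(
    n_clean: int = 8,
    n_promiscuous: int = 4,
    seed: int = 0,
    mutation_rate: float = 0.05,
    relaxed_pseudocount: float = 300.0,
) -> ScreenStudy:
    """Design a screen with clean subgroups and a promiscuous clique.

    Clean subgroups get distinct random motifs and sharp models; the
    promiscuous clique shares one motif pair (overlapping spacer modes)
    and deliberately relaxed, low-information models — promiscuity as weak
    binding specificity. Scanning every promoter with every model yields a
    predicted crosstalk matrix in which the clique shows broad mid-level
    off-target activity while clean pairs stay near baseline.
    """
    rng = np.random.default_rng(seed)
    specs: Dict[int, MotifSpec] = {}
    relaxed: Dict[int, bool] = {}
    for i in range(n_clean):
        specs[i + 1] = MotifSpec(
            consensus35=random_dna(rng, 7),
            consensus10=random_dna(rng, 6),
            per_position_mutation_rate=mutation_rate,
            spacer_distribution={15: 0.2, 16: 0.6, 17: 0.2},
        )
        relaxed[i + 1] = False
    shared35, shared10 = random_dna(rng, 7), random_dna(rng, 6)
    for k in range(n_promiscuous):
        sg = n_clean + k + 1
        mode = 15 + (k % 3)
        specs[sg] = MotifSpec(
            consensus35=shared35,
            consensus10=shared10,
            per_position_mutation_rate=mutation_rate,
            spacer_distribution={mode - 1: 0.2, mode: 0.6, mode + 1: 0.2},
        )
        relaxed[sg] = True
    models = {
        sg: model_from_motif_spec(
            sp, subgroup=sg, pseudocount=relaxed_pseudocount if relaxed[sg] else None
        )
        for sg, sp in specs.items()
    }
    promoters = {
        sg: gen_subgroup_promoters(sp, 1, seed=int(seed) * 1000 + sg, subgroup=sg)[0]
        for sg, sp in specs.items()
    }
    sgs = sorted(specs)
    sigma_ids = [f"ECF{sg % 43 + 1:02d}_9{sg:03d}" for sg in sgs]
    promoter_ids = [promoters[sg].id for sg in sgs]
    return ScreenStudy(
        specs=specs,
        models=models,
        promoters=promoters,
        sigma_ids=sigma_ids,
        promoter_ids=promoter_ids,
        cognate=dict(zip(sigma_ids, promoter_ids)),
        clean_sigma_ids=sigma_ids[:n_clean],
    )


# ---------------------------------------------------------------------------
# Switch transfer functions


def gen_switch_data(params, inputs: Sequence[float], noise_cv: float, seed: int):
    """Noisy transfer function from the sequestration model (lognormal noise)."""
    from .switch_titration import TransferFunction, simulate_transfer

    tf = simulate_transfer(params, inputs)
    rng = np.random.default_rng(seed)
    noisy = np.asarray(tf.outputs) * _lognormal_factors(rng, noise_cv, len(tf.outputs))
    return TransferFunction(inputs=tf.inputs, outputs=noisy.tolist())


# ---------------------------------------------------------------------------
# Presence/absence matrices


def designated_groups(n_subgroups: int) -> Tuple[List[int], List[int]]:
    """Deterministic (insulated, crosstalking) subgroup index groups used by
    the biased presence generator: the first and second quarter of rows."""
    k = max(2, n_subgroups // 4)
    return list(range(k)), list(range(k, 2 * k))


def gen_presence_matrix(
    n_subgroups: int,
    n_genomes: int,
    cooccurrence_bias: float,
    seed: int,
    base_range: Tuple[float, float] = (0.2, 0.8),
):
    """Boolean subgroup x genome matrix with tunable co-occurrence structure.

    Genomes vary in richness (overall presence probability drawn from
    ``base_range``). A positive bias tilts the designated "insulated"
    subgroups toward rich genomes and the designated "crosstalking"
    subgroups away from them, raising / lowering their mean co-occurring
    partner counts; bias 0 makes the two groups exchangeable (null).
    Any all-absent subgroup row is patched by planting one occurrence in
    the richest genome (deterministically), so partner counts are defined.
    """
    from .cooccurrence import PresenceMatrix

    if n_subgroups < 2 or n_genomes < 2:
        raise ValidationError("need at least 2 subgroups and 2 genomes")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, 1, size=n_genomes)
    q = base_range[0] + (base_range[1] - base_range[0]) * u
    probs = np.tile(q, (n_subgroups, 1))
    ins, cross = designated_groups(n_subgroups)
    tilt = cooccurrence_bias * (u - 0.5)
    probs[ins, :] = np.clip(q + tilt, 0.02, 0.98)
    probs[cross, :] = np.clip(q - tilt, 0.02, 0.98)
    present = rng.uniform(size=probs.shape) < probs
    richest = int(np.argmax(q))
    for i in range(n_subgroups):
        if not present[i].any():
            present[i, richest] = True
    return PresenceMatrix(
        subgroup_ids=[f"sg{i:02d}" for i in range(n_subgroups)],
        genome_ids=[f"genome{j:03d}" for j in range(n_genomes)],
        present=present,
    )
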