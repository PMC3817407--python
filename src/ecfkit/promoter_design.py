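"""Genome mining, screening and redesign of candidate ECF promoters, and
combinatorics of chimeric sigma / promoter specificities.

ECF sigmas usually autoregulate: the promoter they recognise sits upstream
of their own gene (or of the operon the gene belongs to). Mining therefore
walks upstream across putative operon members (same strand, short
intergenic gaps) and extracts the regulatory region upstream of the operon
head. Candidates are then scored against every subgroup model, screened
against host sigma70/FecI-like promoters (promoters resembling host motifs
would fire in the chassis), and optionally rebuilt with a synthetic
A/T-rich UP element replacing -60..-36 to boost recognition by the RNAP
alpha subunits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._seq import revcomp, validate_dna
from .errors import ValidationError
from .motif_model import (
    PWM,
    PromoterModel,
    SpacerModel,
    build_pwm,
    scan_promoter,
)
from .roster_io import PromoterRecord, parse_part_id, format_part_id, PartId

DEFAULT_OPERON_GAP = 50  # nt; common prokaryotic operon-calling heuristic
DEFAULT_MAX_UPSTREAM = 300  # nt; typical bacterial regulatory window

# Packaged 25 nt A/T-rich UP element (synthetic sequence; consensus-style
# alternating A/T tracts as described for alpha-subunit recognition).
DEFAULT_UP_ELEMENT = "AAAATTTTTTTGAAAATAAATTTTT"


# ---------------------------------------------------------------------------
# Upstream extraction


@dataclass(frozen=True)
class UpstreamRegion:
    gene_id: str
    region: str  # plus-strand-of-gene orientation
    length: int
    operon_members: List[str]
    truncated: bool


def _annotation_row(annotation: pd.DataFrame, gene_id: str) -> pd.Series:
    hit = annotation[annotation["gene_id"] == gene_id]
    if hit.empty:
        raise ValidationError(f"gene {gene_id!r} not found in annotation")
    return hit.iloc[0]


def extract_upstream(
    genome: str,
    annotation: pd.DataFrame,
    target_gene: str,
    max_len: int = DEFAULT_MAX_UPSTREAM,
    operon_gap: int = DEFAULT_OPERON_GAP,
) -> UpstreamRegion:
    """Regulatory region upstream of a gene's putative operon head.

    Walks upstream (in gene orientation) across same-strand neighbours
    whose intergenic gap is <= ``operon_gap``, then returns up to
    ``max_len`` nt upstream of the operon head, reverse-complemented for
    minus-strand genes. Coordinates are 1-based inclusive. ``truncated``
    is set when the genome edge cuts the region short.
    """
    row = _annotation_row(annotation, target_gene)
    strand = row["strand"]
    contig = annotation[
        (annotation["contig"] == row["contig"]) & (annotation["strand"] == strand)
    ].sort_values("start")
    members = [target_gene]
    current = row
    while True:
        if strand == "+":
            upstreams = contig[contig["end"] < current["start"]]
            if upstreams.empty:
                break
            neighbour = upstreams.iloc[-1]
            gap = current["start"] - neighbour["end"] - 1
        else:
            upstreams = contig[contig["start"] > current["end"]]
            if upstreams.empty:
                break
            neighbour = upstreams.iloc[0]
            gap = neighbour["start"] - current["end"] - 1
        if gap > operon_gap:
            break
        members.append(neighbour["gene_id"])
        current = neighbour
    head = current
    if strand == "+":
        stop = int(head["start"]) - 1  # last upstream base, 1-based
        start = max(1, stop - max_len + 1)
        seq = genome[start - 1 : stop]
        truncated = stop - max_len + 1 < 1
    else:
        start = int(head["end"]) + 1
        stop = min(len(genome), start + max_len - 1)
        seq = revcomp(genome[start - 1 : stop])
        truncated = start + max_len - 1 > len(genome)
    return UpstreamRegion(
        gene_id=target_gene,
        region=seq.upper(),
        length=len(seq),
        operon_members=members[::-1],
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Candidate assessment


@dataclass(frozen=True)
class CandidateAssessment:
    promoter: PromoterRecord
    cognate_score: float
    best_offtarget_score: float
    offtarget_model: Optional[int]  # subgroup of the strongest competitor
    autoregulatory: bool
    host_flagged: bool

    @property
    def margin(self) -> float:
        return self.cognate_score - self.best_offtarget_score


def assess_candidates(
    promoters: Sequence[PromoterRecord],
    models: Sequence[PromoterModel],
    cognate_map: Dict[str, int],
    autoregulatory: Optional[Dict[str, bool]] = None,
    host_models: Optional[Sequence[PromoterModel]] = None,
    host_cutoff: Optional[float] = None,
    flank_nt: int = 0,
) -> List[CandidateAssessment]:
    """Score promoters against all subgroup models and rank for orthogonality.

    Ranking: unflagged before host-flagged, then descending orthogonality
    margin (cognate score minus best off-target score), autoregulatory
    first among ties. With a single model the margin is +inf (no
    competitor).
    """
    by_subgroup = {m.subgroup: m for m in models}
    autoregulatory = autoregulatory or {}
    out = []
    for rec in promoters:
        sg = cognate_map.get(rec.id)
        if sg is None or sg not in by_subgroup:
            raise ValidationError(f"{rec.id}: no model for cognate subgroup {sg!r}")
        seq = rec.with_flanks(flank_nt) if flank_nt else rec.sequence
        cognate_score = scan_promoter(by_subgroup[sg], seq).total
        best_off, best_sg = float("-inf"), None
        for other_sg, model in by_subgroup.items():
            if other_sg == sg:
                continue
            score = scan_promoter(model, seq).total
            if score > best_off:
                best_off, best_sg = score, other_sg
        flagged = (
            host_exclusion_screen(rec, host_models, host_cutoff) if host_models else False
        )
        out.append(
            CandidateAssessment(
                promoter=rec,
                cognate_score=cognate_score,
                best_offtarget_score=best_off,
                offtarget_model=best_sg,
                autoregulatory=bool(autoregulatory.get(rec.id, False)),
                host_flagged=flagged,
            )
        )
    out.sort(key=lambda c: (c.host_flagged, -c.margin, not c.autoregulatory, c.promoter.id))
    return out


# ---------------------------------------------------------------------------
# Host exclusion


def _consensus_model(subgroup: int, c35: str, c10: str, spacer_counts: Dict[int, int]) -> PromoterModel:
    n = sum(spacer_counts.values())
    return PromoterModel(
        subgroup=subgroup,
        pwm35=build_pwm([c35] * n, pseudocount=1.0),
        pwm10=build_pwm([c10] * n, pseudocount=1.0),
        spacer=SpacerModel(counts=spacer_counts, pseudocount=1.0),
    )


def sigma70_model() -> PromoterModel:
    """Housekeeping sigma70 bipartite model from the textbook consensus
    TTGACA / 17 +- 2 nt spacer / TATAAT."""
    return _consensus_model(0, "TTGACA", "TATAAT", {15: 1, 16: 4, 17: 9, 18: 4, 19: 1})


def feci_model() -> PromoterModel:
    """FecI-like host model (synthetic approximation).

    Built from approximate fecA-promoter-style elements (G-rich -35,
    pyrimidine-rich -10); the true FecI specificity is not published as a
    clean consensus, so this fixture only needs to be representative
    enough to flag FecI-like promoter sequences.
    """
    return _consensus_model(0, "GGAAAT", "TCCTTT", {15: 2, 16: 6, 17: 2})


def default_host_models() -> List[PromoterModel]:
    return [sigma70_model(), feci_model()]


def host_exclusion_screen(
    promoter: PromoterRecord,
    host_models: Optional[Sequence[PromoterModel]] = None,
    cutoff: Optional[float] = None,
) -> bool:
    """Flag promoters resembling host (sigma70 / FecI-like) promoters.

    Flagged iff any host model scans the window at >= cutoff. The default
    cutoff is that model's consensus score minus 6 bits.
    """
    models = list(host_models) if host_models else default_host_models()
    for model in models:
        this_cutoff = model.consensus_score() - 6.0 if cutoff is None else cutoff
        if math.isinf(this_cutoff) and this_cutoff > 0:
            continue  # +inf cutoff: never flag
        if scan_promoter(model, promoter.sequence).total >= this_cutoff:
            return True
    return False


# ---------------------------------------------------------------------------
# UP element replacement


def apply_up_element(promoter: PromoterRecord, up_seq: str = DEFAULT_UP_ELEMENT) -> PromoterRecord:
    """Replace the -60..-36 region with a synthetic A/T-rich UP element.

    The window must start at -60; the replacement length equals the
    -60..-36 span (25 nt), so total length is unchanged and everything
    from -35 on is untouched. The id is renamed P_XX_YYYY -> P_XX_UPYYYY.
    """
    if promoter.window[0] != -60:
        raise ValidationError(f"{promoter.id}: window must start at -60 to install an UP element")
    up_seq = validate_dna(up_seq, context="UP element")
    span = 25  # positions -60..-36 inclusive
    if len(up_seq) != span:
        raise ValidationError(f"UP element must be {span} nt (got {len(up_seq)})")
    part = parse_part_id(promoter.id)
    if part.kind != "promoter":
        raise ValidationError(f"{promoter.id}: not a promoter id")
    new_id = format_part_id(PartId("promoter", part.subgroup, part.uid, up=True))
    new_seq = up_seq + promoter.sequence[span:]
    return replace(promoter, id=new_id, sequence=new_seq, up_modified=True)


# ---------------------------------------------------------------------------
# Chimera combinatorics


@dataclass(frozen=True)
class SpecificityClasses:
    """Per-subgroup -35 and -10 binding-specificity class labels."""

    classes35: Dict[int, str]
    classes10: Dict[int, str]

    def __post_init__(self):
        if not self.classes35 or not self.classes10:
            raise ValidationError("class maps must be non-empty")
        if set(self.classes35) != set(self.classes10):
            raise ValidationError("every modeled subgroup needs both class labels")


def enumerate_chimeras(
    classes: SpecificityClasses,
) -> Tuple[int, List[Tuple[str, str]], List[Tuple[str, str]]]:
    """Upper bound on orthogonal sigmas by domain recombination.

    Returns (count, all class35 x class10 combinations, the novel subset
    not realised by any natural subgroup). count = |distinct -35 classes|
    x |distinct -10 classes|.
    """
    set35 = sorted(set(classes.classes35.values()))
    set10 = sorted(set(classes.classes10.values()))
    natural = {
        (classes.classes35[sg], classes.classes10[sg]) for sg in classes.classes35
    }
    combos = [(a, b) for a in set35 for b in set10]
    novel = [c for c in combos if c not in natural]
    return len(set35) * len(set10), combos, novel


def build_chimeric_promoter(
    donor35: PromoterModel,
    donor10: PromoterModel,
    spacer: int,
    context: PromoterRecord,
) -> PromoterRecord:
    """Install donor -35 and -10 consensus blocks into a promoter context.

    The -10 block keeps the canonical register (its 3' end at position -7);
    the requested spacer then sets where the -35 consensus lands. The
    spacer must lie within the union of the two donors' supports. Sequence
    downstream of the -10 element is unchanged.
    """
    supports = set(range(*donor35.spacer.support)) | {donor35.spacer.support[1]}
    supports |= set(range(*donor10.spacer.support)) | {donor10.spacer.support[1]}
    if spacer not in supports:
        raise ValidationError(
            f"spacer {spacer} outside the donors' supports "
            f"{donor35.spacer.support} / {donor10.spacer.support}"
        )
    c35 = donor35.pwm35.consensus
    c10 = donor10.pwm10.consensus
    end10 = context.position_to_index(-7) + 1
    start10 = end10 - len(c10)
    start35 = start10 - spacer - len(c35)
    if start35 < 0:
        raise ValidationError("chimeric footprint does not fit the context window")
    seq = list(context.sequence)
    seq[start35 : start35 + len(c35)] = c35
    seq[start10:end10] = c10
    uid = f"CH{donor35.subgroup:02d}{donor10.subgroup:02d}S{spacer}"
    new_id = format_part_id(PartId("promoter", donor35.subgroup, uid))
    return replace(context, id=new_id, sequence="".join(seq), source="chimeric promoter")
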