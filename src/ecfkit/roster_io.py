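"""Data model, naming conventions and file I/O for part-library rosters.

Naming conventions follow the field's part-naming scheme: sigmas are
``ECFXX_YYYY`` (XX = zero-padded subgroup, YYYY = unique id), anti-sigmas
``ASXX_YYYY`` with the numbering of their cognate sigma, and promoters
``P_XX_YYYY`` or ``P_XX_UPYYYY`` once an UP element has been installed.
Promoter windows use bacterial promoter coordinates (default -60..+20,
no position 0); internally sequences are stored 0-based and accessors
expose the offset map.

All TSVs are tab-delimited UTF-8 with a mandatory header row; lines
starting with '#' are comments. FASTA I/O goes through Biopython.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import validate_dna
from .errors import ParseError, ValidationError
from .motif_model import PWM, PromoterModel, SpacerModel

logger = logging.getLogger("ecfkit")

SIGMA_ID_RE = re.compile(r"^ECF(\d{2})_([0-9A-Za-z]+)$")
ANTI_ID_RE = re.compile(r"^AS(\d{2})_([0-9A-Za-z]+)$")
PROMOTER_ID_RE = re.compile(r"^P_(\d{2})_(UP)?([0-9A-Za-z]+)$")


@dataclass(frozen=True)
class PartId:
    kind: str  # "sigma" | "anti" | "promoter"
    subgroup: int
    uid: str
    up: bool = False


def parse_part_id(part_id: str) -> PartId:
    """Parse any library part id; inverse of format_part_id."""
    m = SIGMA_ID_RE.match(part_id)
    if m:
        return PartId("sigma", int(m.group(1)), m.group(2))
    m = ANTI_ID_RE.match(part_id)
    if m:
        return PartId("anti", int(m.group(1)), m.group(2))
    m = PROMOTER_ID_RE.match(part_id)
    if m:
        return PartId("promoter", int(m.group(1)), m.group(3), up=m.group(2) is not None)
    raise ValidationError(f"id {part_id!r} matches no library naming convention")


def format_part_id(part: PartId) -> str:
    if part.kind == "promoter":
        if part.uid.startswith("UP"):
            # reserved prefix would make parsing ambiguous
            raise ValidationError(f"promoter uid may not start with 'UP': {part.uid!r}")
        return f"P_{part.subgroup:02d}_{'UP' if part.up else ''}{part.uid}"
    if part.up:
        raise ValidationError("only promoters carry the UP flag")
    prefix = {"sigma": "ECF", "anti": "AS"}.get(part.kind)
    if prefix is None:
        raise ValidationError(f"unknown part kind {part.kind!r}")
    return f"{prefix}{part.subgroup:02d}_{part.uid}"


# ---------------------------------------------------------------------------
# Domain records


@dataclass
class SigmaRecord:
    id: str
    subgroup: int
    source_organism: str = ""
    domain2_class: str = ""  # -10 specificity class
    domain4_class: str = ""  # -35 specificity class
    active: bool = False

    def problems(self) -> List[str]:
        out = []
        try:
            p = parse_part_id(self.id)
            if p.kind != "sigma":
                out.append(f"{self.id}: not a sigma id")
            elif p.subgroup != self.subgroup:
                out.append(f"{self.id}: id subgroup {p.subgroup} != field {self.subgroup}")
        except ValidationError as exc:
            out.append(str(exc))
        if not 1 <= self.subgroup <= 43:
            out.append(f"{self.id}: subgroup {self.subgroup} outside 1..43")
        return out


@dataclass
class AntiSigmaRecord:
    id: str
    cognate_sigma_id: str
    active: bool = False

    def problems(self) -> List[str]:
        out = []
        try:
            p = parse_part_id(self.id)
            if p.kind != "anti":
                out.append(f"{self.id}: not an anti-sigma id")
            else:
                c = parse_part_id(self.cognate_sigma_id)
                if (c.subgroup, c.uid) != (p.subgroup, p.uid):
                    out.append(
                        f"{self.id}: numbering does not match cognate {self.cognate_sigma_id}"
                    )
        except ValidationError as exc:
            out.append(str(exc))
        return out


@dataclass
class PromoterRecord:
    """A promoter window (-60..+20 by default) with optional vector flanks."""

    id: str
    sequence: str
    window: Tuple[int, int] = (-60, 20)
    flank5: str = ""
    flank3: str = ""
    up_modified: bool = False
    source: str = ""

    def __post_init__(self):
        self.sequence = validate_dna(self.sequence, context=self.id)
        self.flank5 = validate_dna(self.flank5, context=f"{self.id} flank5")
        self.flank3 = validate_dna(self.flank3, context=f"{self.id} flank3")

    @property
    def span(self) -> int:
        """Window length in nt; promoter coordinates have no position 0."""
        start, stop = self.window
        if not (start < 0 < stop):
            raise ValidationError(f"{self.id}: window must straddle the +1 site")
        return stop - start

    def position_to_index(self, pos: int) -> int:
        """Map a promoter coordinate (no 0) to a 0-based sequence index."""
        start, stop = self.window
        if pos == 0 or pos < start or pos > stop:
            raise ValidationError(f"{self.id}: position {pos} outside window {self.window}")
        return pos - start if pos < 0 else pos - start - 1

    def with_flanks(self, n: int = 30) -> str:
        """Window sequence plus up to n nt of vector context on each side."""
        return (self.flank5[-n:] if n else "") + self.sequence + (self.flank3[:n] if n else "")

    def problems(self) -> List[str]:
        out = []
        try:
            p = parse_part_id(self.id)
            if p.kind != "promoter":
                out.append(f"{self.id}: not a promoter id")
            elif p.up != self.up_modified:
                out.append(f"{self.id}: UP flag in id disagrees with up_modified field")
        except ValidationError as exc:
            out.append(str(exc))
        try:
            if len(self.sequence) != self.span:
                out.append(
                    f"{self.id}: sequence length {len(self.sequence)} != window span {self.span}"
                )
        except ValidationError as exc:
            out.append(str(exc))
        if "N" in self.sequence:
            out.append(f"{self.id}: ambiguous base N not allowed in promoter windows")
        return out


@dataclass
class LibraryRoster:
    sigmas: List[SigmaRecord] = field(default_factory=list)
    anti_sigmas: List[AntiSigmaRecord] = field(default_factory=list)
    promoters: List[PromoterRecord] = field(default_factory=list)

    def sigma(self, sigma_id: str) -> SigmaRecord:
        for s in self.sigmas:
            if s.id == sigma_id:
                return s
        raise KeyError(sigma_id)

    def validate(self) -> None:
        problems: List[str] = []
        for rec in [*self.sigmas, *self.anti_sigmas, *self.promoters]:
            problems.extend(rec.problems())
        sigma_ids = {s.id for s in self.sigmas}
        for a in self.anti_sigmas:
            if a.cognate_sigma_id not in sigma_ids:
                problems.append(f"{a.id}: dangling cognate reference {a.cognate_sigma_id}")
        for name, ids in (
            ("sigma", [s.id for s in self.sigmas]),
            ("anti", [a.id for a in self.anti_sigmas]),
            ("promoter", [p.id for p in self.promoters]),
        ):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                problems.append(f"duplicate {name} ids: {sorted(dupes)}")
        if problems:
            raise ValidationError(problems)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA records as (id, upper-case sequence) pairs.

    Sequences are validated against {A,C,G,T,N}; empty files and empty
    records raise ParseError naming the offender.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            seq = validate_dna(seq, allow_n=True, context=rec.id)
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from None
        records.append((rec.id, seq))
    if not records:
        raise ParseError(f"{path}: no records")
    return records


def write_fasta(records: Sequence[Tuple[str, str]], path) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqrecs, str(path), "fasta")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


_TRUE = {"1", "true", "yes"}


def load_roster(
    sigma_tsv,
    anti_tsv,
    promoter_fasta,
    promoter_meta_tsv=None,
) -> LibraryRoster:
    """Load and cross-validate a full library roster.

    sigma TSV columns: id, subgroup, organism, domain2_class, domain4_class
    [, active]; anti TSV: id, cognate_sigma_id [, active]; promoter
    metadata TSV (optional) keyed by FASTA id: id, window_start, window_end,
    flank5, flank3, up_modified, source.
    """
    sdf = _read_tsv(sigma_tsv)
    sigmas = [
        SigmaRecord(
            id=r["id"],
            subgroup=int(r["subgroup"]),
            source_organism=r.get("organism", ""),
            domain2_class=r.get("domain2_class", ""),
            domain4_class=r.get("domain4_class", ""),
            active=str(r.get("active", "")).lower() in _TRUE,
        )
        for r in sdf.to_dict("records")
    ]
    adf = _read_tsv(anti_tsv)
    antis = [
        AntiSigmaRecord(
            id=r["id"],
            cognate_sigma_id=r["cognate_sigma_id"],
            active=str(r.get("active", "")).lower() in _TRUE,
        )
        for r in adf.to_dict("records")
    ]
    meta: Dict[str, dict] = {}
    if promoter_meta_tsv is not None:
        meta = {r["id"]: r for r in _read_tsv(promoter_meta_tsv).to_dict("records")}
    promoters = []
    for name, seq in read_fasta(promoter_fasta):
        m = meta.get(name, {})
        window = (int(m.get("window_start", -60)), int(m.get("window_end", 20)))
        try:
            up = parse_part_id(name).up
        except ValidationError:
            up = False
        promoters.append(
            PromoterRecord(
                id=name,
                sequence=seq,
                window=window,
                flank5=m.get("flank5", ""),
                flank3=m.get("flank3", ""),
                up_modified=str(m.get("up_modified", up)).lower() in (_TRUE | {"true"})
                if m
                else up,
                source=m.get("source", ""),
            )
        )
    roster = LibraryRoster(sigmas=sigmas, anti_sigmas=antis, promoters=promoters)
    roster.validate()
    logger.info(
        "loaded roster: %d sigmas, %d anti-sigmas, %d promoters",
        len(sigmas),
        len(antis),
        len(promoters),
    )
    return roster


def write_roster(roster: LibraryRoster, sigma_tsv, anti_tsv, promoter_fasta, promoter_meta_tsv):
    """Serialize a roster to the same files load_roster reads (lossless)."""
    pd.DataFrame(
        [
            {
                "id": s.id,
                "subgroup": s.subgroup,
                "organism": s.source_organism,
                "domain2_class": s.domain2_class,
                "domain4_class": s.domain4_class,
                "active": int(s.active),
            }
            for s in roster.sigmas
        ]
    ).to_csv(sigma_tsv, sep="\t", index=False)
    pd.DataFrame(
        [
            {"id": a.id, "cognate_sigma_id": a.cognate_sigma_id, "active": int(a.active)}
            for a in roster.anti_sigmas
        ]
    ).to_csv(anti_tsv, sep="\t", index=False)
    write_fasta([(p.id, p.sequence) for p in roster.promoters], promoter_fasta)
    pd.DataFrame(
        [
            {
                "id": p.id,
                "window_start": p.window[0],
                "window_end": p.window[1],
                "flank5": p.flank5,
                "flank3": p.flank3,
                "up_modified": int(p.up_modified),
                "source": p.source,
            }
            for p in roster.promoters
        ]
    ).to_csv(promoter_meta_tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format for bipartite promoter models


def write_motif_minimal(model: PromoterModel, path) -> None:
    """Write both PWMs in MEME minimal format, one motif block each.

    The spacer histogram, support and model metadata ride in '#' comment
    lines before the MEME header so the companion reader round-trips the
    full bipartite model losslessly (probabilities to 6 decimals).
    """
    if model.pwm35.width == 0 or model.pwm10.width == 0:
        raise ValidationError("cannot serialize a zero-width PWM")
    if not np.allclose(model.pwm35.background, model.pwm10.background):
        raise ValidationError("both PWMs must share one background for MEME output")
    bg = model.pwm35.background
    counts = " ".join(f"{k}:{v}" for k, v in sorted(model.spacer.counts.items()))
    lines = [
        f"# ecfkit-promoter-model subgroup={model.subgroup}",
        f"# spacer_counts {counts}",
        f"# spacer_support {model.spacer.support[0]}-{model.spacer.support[1]}",
        f"# spacer_pseudocount {model.spacer.pseudocount}",
        f"# pwm_pseudocount {model.pwm35.pseudocount}",
        f"# up_bonus {model.up_bonus}",
        f"# up_width {model.up_width}",
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "Background letter frequencies",
        f"A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}",
        "",
    ]
    total_sites = sum(model.spacer.counts.values())
    for name, pwm in ((f"ECF{model.subgroup:02d}_35", model.pwm35), (f"ECF{model.subgroup:02d}_10", model.pwm10)):
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= {max(total_sites, 1)} E= 0"
        )
        for row in pwm.probs:
            lines.append(" " + " ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_motif_minimal(path) -> PromoterModel:
    """Companion reader for write_motif_minimal."""
    text = Path(path).read_text()
    meta: Dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("# ") and " " in line[2:]:
            key, _, val = line[2:].partition(" ")
            meta[key] = val.strip()
    bg = None
    matrices: List[np.ndarray] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("letter-probability matrix"):
            m = re.search(r"w=\s*(\d+)", line)
            w = int(m.group(1))
            rows = [[float(x) for x in lines[i + 1 + j].split()] for j in range(w)]
            matrices.append(np.array(rows))
            i += 1 + w
            continue
        i += 1
    if bg is None or len(matrices) != 2:
        raise ParseError(f"{path}: expected a background line and exactly two motifs")
    # renormalize 6-decimal rounding so PWM invariants hold exactly
    matrices = [m / m.sum(axis=1, keepdims=True) for m in matrices]
    counts = {}
    if meta.get("spacer_counts"):
        for tok in meta["spacer_counts"].split():
            k, _, v = tok.partition(":")
            counts[int(k)] = int(v)
    lo, _, hi = meta["spacer_support"].partition("-")
    pc = float(meta.get("pwm_pseudocount", 0.0))
    return PromoterModel(
        subgroup=int(meta.get("ecfkit-promoter-model", "subgroup=0").split("=")[1]),
        pwm35=PWM(probs=matrices[0], background=bg, pseudocount=pc),
        pwm10=PWM(probs=matrices[1], background=bg, pseudocount=pc),
        spacer=SpacerModel(
            counts=counts,
            pseudocount=float(meta.get("spacer_pseudocount", 1.0)),
            support=(int(lo), int(hi)),
        ),
        up_bonus=float(meta.get("up_bonus", 0.0)),
        up_width=int(meta.get("up_width", 23)),
    )
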