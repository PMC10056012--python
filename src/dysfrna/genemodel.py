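"""Transcript coordinate model, variant representation, and reading-frame rules.

Everything downstream (allele-imbalance phasing, splice quantification, CNV
flagging) shares this coordinate system: HGVS c.-style 1-based transcript
positions with symbolic intronic offsets (``c.2810+1`` stays ``(2810, +1)``;
no genome build is ever consulted).  The bundled default model is a
*synthetic* DYSF-like transcript: 55 contiguous coding exons whose boundaries
honour the coordinate anchors implied by published DYSF variant nomenclature
(exon 4 = c.237–342, exon 17 starting at c.1481, exon 26 donor at c.2810,
exon 43 = c.4639–4794, exon 52 = c.5768–5926, ...), with the remaining
boundaries invented at plausible lengths.  Exon 17 is marked variable because
blood DYSF transcripts mostly splice it out.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

__all__ = [
    "TxPos",
    "Exon",
    "GeneModel",
    "Variant",
    "Haplotype",
    "HgvsParseError",
    "CoordinateError",
    "ContractError",
    "parse_hgvs_position",
    "nmd_triggering",
    "frame_consequence",
    "locate",
    "load_default_model",
]

PTV_CLASSES = {"nonsense", "frameshift_indel"}
VARIANT_CLASSES = {
    "missense",
    "nonsense",
    "frameshift_indel",
    "inframe_indel",
    "splice_site",
    "intronic",
    "exonic_deletion",
    "exonic_duplication",
    "synonymous",
}


class HgvsParseError(ValueError):
    """Raised when an HGVS c. position cannot be parsed."""


class CoordinateError(ValueError):
    """Raised when a position does not map into the gene model."""


class ContractError(ValueError):
    """Raised when an operation is called outside its contract."""


@dataclass(frozen=True, order=True)
class TxPos:
    """Transcript position: 1-based coding base plus symbolic intronic offset.

    Ordering is lexicographic on (base, offset), which sorts intron-upstream
    positions (negative offset) before the exon base and intron-downstream
    (positive offset) after it — the natural transcript order.
    """

    base: int
    offset: int = 0

    def __str__(self) -> str:
        if self.offset > 0:
            return f"{self.base}+{self.offset}"
        if self.offset < 0:
            return f"{self.base}{self.offset}"
        return str(self.base)

    @classmethod
    def parse(cls, text: str) -> "TxPos":
        m = re.fullmatch(r"(\d+)([+-]\d+)?", text.strip())
        if not m:
            raise HgvsParseError(f"unparseable transcript position: {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))


_HGVS_POS_RE = re.compile(r"c\.\s?(\d+[+-]?\d*)(?:_(\d+[+-]?\d*))?")


def parse_hgvs_position(hgvs_c: str) -> tuple[TxPos, Optional[TxPos]]:
    """Extract (start, optional end) transcript positions from an HGVS c. string.

    Handles substitutions (c.857T>A), intronic offsets (c.2810+1G>A,
    c.5668-824C>T), and spans (c.2512_3174del, c.1171_1180+4dup14).  The full
    HGVS grammar is out of scope; only the position fields are interpreted.
    """
    m = _HGVS_POS_RE.search(hgvs_c.replace(" ", ""))
    if not m:
        raise HgvsParseError(f"no c. position found in {hgvs_c!r}")
    start = TxPos.parse(m.group(1))
    end = TxPos.parse(m.group(2)) if m.group(2) else None
    return start, end


@dataclass(frozen=True)
class Exon:
    exon_id: int
    start: int  # 1-based inclusive, transcript coordinates
    end: int    # 1-based inclusive
    coding: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """Exon/intron structure of a declared reference transcript."""

    transcript_id: str
    exons: list[Exon]
    variable_exons: dict[int, float] = field(default_factory=dict)
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.exons) < 2:
            raise ValueError("a gene model needs at least 2 exons")
        prev_end = 0
        for ex in self.exons:
            if ex.start <= prev_end:
                raise ValueError(
                    f"exons must be ordered and non-overlapping (exon {ex.exon_id})"
                )
            if ex.end < ex.start:
                raise ValueError(f"exon {ex.exon_id} has end < start")
            prev_end = ex.end
        known = {ex.exon_id for ex in self.exons}
        for eid, frac in self.variable_exons.items():
            if eid not in known:
                raise ValueError(f"variable exon {eid} is not in the model")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"inclusion fraction for exon {eid} outside [0,1]")
        self._by_id = {ex.exon_id: ex for ex in self.exons}

    # -- lookups -----------------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def last_exon(self) -> Exon:
        return self.exons[-1]

    @property
    def penultimate_exon(self) -> Exon:
        return self.exons[-2]

    def exon(self, exon_id: int) -> Exon:
        try:
            return self._by_id[exon_id]
        except KeyError:
            raise CoordinateError(f"no exon {exon_id} in {self.transcript_id}")

    def exon_index(self, exon_id: int) -> int:
        for i, ex in enumerate(self.exons):
            if ex.exon_id == exon_id:
                return i
        raise CoordinateError(f"no exon {exon_id} in {self.transcript_id}")

    def exon_containing(self, base: int) -> Exon:
        for ex in self.exons:
            if ex.start <= base <= ex.end:
                return ex
        raise CoordinateError(
            f"position {base} outside transcript {self.transcript_id} "
            f"(1..{self.last_exon.end})"
        )

    def canonical_junctions(self) -> list[tuple[TxPos, TxPos]]:
        """Donor/acceptor pairs of every reference exon–exon junction."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append((TxPos(a.end), TxPos(b.start)))
        return out

    def inclusion_fraction(self, exon_id: int) -> float:
        return self.variable_exons.get(exon_id, 1.0)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "strand": self.strand,
            "exons": [
                {
                    "exon_id": ex.exon_id,
                    "start": ex.start,
                    "end": ex.end,
                    "coding": ex.coding,
                }
                for ex in self.exons
            ],
            "variable_exons": {str(k): v for k, v in self.variable_exons.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            transcript_id=d["transcript_id"],
            exons=[
                Exon(e["exon_id"], e["start"], e["end"], e.get("coding", True))
                for e in d["exons"]
            ],
            variable_exons={int(k): float(v) for k, v in d.get("variable_exons", {}).items()},
            strand=d.get("strand", "+"),
        )

    @classmethod
    def from_json(cls, path) -> "GeneModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def load_default_model() -> GeneModel:
    """The bundled synthetic DYSF-like 55-exon model (exon 17 variable)."""
    ref = resources.files("dysfrna.data").joinpath("synthetic_dysf_model.json")
    return GeneModel.from_dict(json.loads(ref.read_text()))


@dataclass
class Variant:
    """A variant in HGVS c. nomenclature on the declared transcript."""

    id: str
    v_class: str
    zygosity: str = "het"
    allele: Optional[str] = None  # haplotype label "A"/"B", if assigned
    is_ptv: Optional[bool] = None  # override for frameshifting splice/CNV events

    def __post_init__(self) -> None:
        if self.v_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.v_class!r}")
        if self.is_ptv is None:
            self.is_ptv = self.v_class in PTV_CLASSES
        self.position, self.span_end = parse_hgvs_position(self.id)


@dataclass
class Haplotype:
    allele_id: str  # "A" or "B"
    variants: list[Variant] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rules


def frame_consequence(nt_count: int, kind: str = "deletion") -> str:
    """Classify a deletion/insertion of ``nt_count`` nucleotides by reading frame."""
    if kind not in ("deletion", "insertion"):
        raise ContractError(f"kind must be deletion or insertion, got {kind!r}")
    if nt_count < 1:
        raise ContractError(f"nt_count must be >= 1, got {nt_count}")
    return "in_frame" if nt_count % 3 == 0 else "frameshift"


def nmd_triggering(variant: Variant, model: GeneModel, escape_window: int = 50) -> bool:
    """Whether a PTV is expected to trigger nonsense-mediated decay.

    A PTV escapes decay when it lies in the last exon or within
    ``escape_window`` nt upstream of the final exon–exon junction (the
    conventional 50-nt rule); it triggers decay otherwise.
    """
    if not variant.is_ptv:
        raise ContractError(f"{variant.id} is not a protein-truncating variant")
    ex = model.exon_containing(variant.position.base)
    if ex.exon_id == model.last_exon.exon_id:
        return False
    penult = model.penultimate_exon
    if ex.exon_id == penult.exon_id and variant.position.base > penult.end - escape_window:
        return False
    return True


def locate(variant: Variant, model: GeneModel) -> tuple[str, bool]:
    """Containing feature of a variant and whether it sits in a variable exon.

    Intronic offsets are resolved relative to the anchor exon: ``c.X+n`` lies
    in the intron downstream of the exon containing X, ``c.X-n`` in the intron
    upstream.  The variable-exon flag reports on the anchor exon, so acceptor/
    donor variants of a variable exon are flagged too.
    """
    pos = variant.position
    ex = model.exon_containing(pos.base)
    in_variable = ex.exon_id in model.variable_exons
    if pos.offset == 0:
        return f"exon {ex.exon_id}", in_variable
    if pos.offset > 0:
        return f"intron {ex.exon_id}", in_variable
    return f"intron {ex.exon_id - 1}", in_variable
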