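"""ACMG/AMP evidence combination and reclassification accounting.

Evidence codes arrive as inputs (population, computational, functional and
phenotype evidence assembled upstream); this module owns the combining rules
that map a set of codes — with optional strength modifiers, e.g. PM3
upgraded to strong when multiple unrelated trans observations accumulate —
onto the five-tier scale, and the bookkeeping that compares study
classifications with prior calls from public databases.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "EvidenceCode",
    "EvidenceSet",
    "Classification",
    "combine",
    "batch_classify",
    "normalize_prior_call",
    "reclassification_diff",
    "PATHOGENIC_CODES",
    "BENIGN_CODES",
]

PATHOGENIC_CODES = (
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_CODES = (
    {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)
_DEFAULT_STRENGTH = {
    "PVS": "very_strong", "PS": "strong", "PM": "moderate", "PP": "supporting",
    "BA": "stand_alone", "BS": "strong", "BP": "supporting",
}
STRENGTHS = {"stand_alone", "very_strong", "strong", "moderate", "supporting"}

TIERS = ("Pathogenic", "Likely_Pathogenic", "VUS", "Likely_Benign", "Benign")


@dataclass(frozen=True)
class EvidenceCode:
    code: str
    strength: Optional[str] = None  # override; None = the code's default
    note: str = ""

    def __post_init__(self) -> None:
        if self.code not in PATHOGENIC_CODES | BENIGN_CODES:
            raise ValueError(f"unknown ACMG/AMP code {self.code!r}")
        if self.strength is not None and self.strength not in STRENGTHS:
            raise ValueError(f"unknown strength {self.strength!r}")

    @property
    def direction(self) -> str:
        return "pathogenic" if self.code in PATHOGENIC_CODES else "benign"

    @property
    def effective_strength(self) -> str:
        if self.strength is not None:
            return self.strength
        return _DEFAULT_STRENGTH[re.match(r"[A-Z]+", self.code).group(0)]


@dataclass
class EvidenceSet:
    variant_id: str
    codes: tuple[EvidenceCode, ...] = ()

    def __post_init__(self) -> None:
        names = [c.code for c in self.codes]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate evidence codes for {self.variant_id}: {sorted(names)}"
            )


@dataclass(frozen=True)
class Classification:
    tier: str
    fired_rule: str


def _strength_counts(codes: Iterable[EvidenceCode]) -> tuple[Counter, Counter]:
    path, benign = Counter(), Counter()
    for c in codes:
        (path if c.direction == "pathogenic" else benign)[c.effective_strength] += 1
    return path, benign


def combine(evidence: EvidenceSet) -> Classification:
    """Combine an evidence set into a five-tier classification.

    Standard combining table; pathogenic tiers are checked before likely
    tiers, and a simultaneously fired pathogenic and benign tier (or nothing
    firing) yields VUS.
    """
    p, b = _strength_counts(evidence.codes)
    vs, st, mo, su = p["very_strong"], p["strong"], p["moderate"], p["supporting"]
    ba, bst, bsu = b["stand_alone"], b["strong"], b["supporting"]

    path_rule = None
    if vs >= 1 and (st >= 1 or mo >= 2 or (mo >= 1 and su >= 1) or su >= 2):
        path_rule = ("Pathogenic", "very_strong + corroboration")
    elif st >= 2:
        path_rule = ("Pathogenic", ">=2 strong")
    elif st >= 1 and (mo >= 3 or (mo >= 2 and su >= 2) or (mo >= 1 and su >= 4)):
        path_rule = ("Pathogenic", "strong + moderate/supporting weight")
    elif vs >= 1 and mo >= 1:
        path_rule = ("Likely_Pathogenic", "very_strong + 1 moderate")
    elif st >= 1 and mo >= 1:
        path_rule = ("Likely_Pathogenic", "strong + 1-2 moderate")
    elif st >= 1 and su >= 2:
        path_rule = ("Likely_Pathogenic", "strong + >=2 supporting")
    elif mo >= 3:
        path_rule = ("Likely_Pathogenic", ">=3 moderate")
    elif mo >= 2 and su >= 2:
        path_rule = ("Likely_Pathogenic", "2 moderate + >=2 supporting")
    elif mo >= 1 and su >= 4:
        path_rule = ("Likely_Pathogenic", "1 moderate + >=4 supporting")

    benign_rule = None
    if ba >= 1:
        benign_rule = ("Benign", "stand-alone benign")
    elif bst >= 2:
        benign_rule = ("Benign", ">=2 benign strong")
    elif bst >= 1 and bsu >= 1:
        benign_rule = ("Likely_Benign", "benign strong + supporting")
    elif bsu >= 2:
        benign_rule = ("Likely_Benign", ">=2 benign supporting")

    if path_rule and benign_rule:
        return Classification("VUS", f"conflict: {path_rule[1]} vs {benign_rule[1]}")
    if path_rule:
        return Classification(*path_rule)
    if benign_rule:
        return Classification(*benign_rule)
    return Classification("VUS", "no combining rule fired")


def _parse_codes(spec: str | Sequence) -> tuple[EvidenceCode, ...]:
    """Parse 'PVS1,PM3:strong,PP4' style code lists."""
    if isinstance(spec, str):
        items = [s.strip() for s in spec.split(",") if s.strip()]
    else:
        items = list(spec)
    out = []
    for it in items:
        if isinstance(it, EvidenceCode):
            out.append(it)
        elif ":" in it:
            code, strength = it.split(":", 1)
            out.append(EvidenceCode(code.strip(), strength.strip()))
        else:
            out.append(EvidenceCode(it))
    return tuple(out)


def batch_classify(
    evidence: Sequence[EvidenceSet] | pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Classify a batch of evidence sets; per-variant failures are reported
    in-table without aborting the batch.

    Accepts either EvidenceSet objects or a DataFrame with columns
    ``variant_id`` and ``codes`` (comma-separated, ``CODE:strength`` for
    overrides).  The summary reports tier counts and the share of variants
    resolved out of VUS.
    """
    sets: list[tuple[str, Optional[EvidenceSet], Optional[str]]] = []
    if isinstance(evidence, pd.DataFrame):
        for _, row in evidence.iterrows():
            vid = str(row["variant_id"])
            try:
                sets.append((vid, EvidenceSet(vid, _parse_codes(row["codes"])), None))
            except ValueError as exc:
                sets.append((vid, None, str(exc)))
    else:
        sets = [(es.variant_id, es, None) for es in evidence]

    rows = []
    for vid, es, err in sets:
        if err is not None:
            rows.append({"variant_id": vid, "tier": "", "fired_rule": "", "error": err})
            continue
        cls = combine(es)
        rows.append({
            "variant_id": vid, "tier": cls.tier,
            "fired_rule": cls.fired_rule, "error": "",
        })
    table = pd.DataFrame(rows, columns=["variant_id", "tier", "fired_rule", "error"])
    valid = table[table["error"] == ""]
    counts = {t: int((valid["tier"] == t).sum()) for t in TIERS}
    n = len(valid)
    resolved = n - counts["VUS"]
    summary = {
        "n": n,
        "counts": counts,
        "n_resolved": resolved,
        "resolved_share_pct": round(100.0 * resolved / n) if n else 0,
        "n_errors": int((table["error"] != "").sum()),
    }
    return table, summary


# ---------------------------------------------------------------------------
# prior-call normalization and reclassification diff

_TOKEN_MAP = {
    "pathogenic": "P",
    "likely pathogenic": "LP",
    "vus": "VUS",
    "likely benign": "LB",
    "benign": "B",
}
PRIOR_CATEGORIES = {"P", "LP", "P/LP", "VUS", "LB", "B", "B/LB",
                    "conflicting", "novel", "unrated"}
_TIER_SHORT = {
    "Pathogenic": "P", "Likely_Pathogenic": "LP", "Likely Pathogenic": "LP",
    "VUS": "VUS", "Likely_Benign": "LB", "Likely Benign": "LB", "Benign": "B",
}
_RANK = {"P": 2, "P/LP": 1.5, "LP": 1, "VUS": 0, "LB": -1, "B/LB": -1.5, "B": -2}


def normalize_prior_call(text: str) -> str:
    """Collapse a free-text prior pathogenicity annotation to a category.

    Consistent same-direction pairs (P + LP, B + LB) stay a single category;
    any mixture involving VUS or crossing direction is conflicting.
    """
    t = str(text).strip()
    if not t or t.lower() in ("novel", "novel variant", "nan"):
        return "novel"
    if t.lower().startswith("of the type") or t.lower() in ("unrated", "not rated"):
        return "unrated"
    t = re.sub(r"\([^)]*\)", "", t).strip()  # drop source annotations
    tokens = set()
    for part in re.split(r"[/,]", t):
        p = part.strip().lower()
        if p in _TOKEN_MAP:
            tokens.add(_TOKEN_MAP[p])
    if not tokens:
        return "unrated"
    if len(tokens) == 1:
        return tokens.pop()
    if tokens == {"P", "LP"}:
        return "P/LP"
    if tokens == {"B", "LB"}:
        return "B/LB"
    return "conflicting"


def _transition(prior: str, current_tier: str) -> str:
    cur = _TIER_SHORT.get(current_tier, current_tier)
    if prior in ("novel", "unrated"):
        return "novel_classified"
    if prior in ("VUS", "conflicting"):
        return "resolved_from_VUS" if cur != "VUS" else "unchanged"
    if prior == "P/LP" and cur in ("P", "LP"):
        return "unchanged"
    if prior == "B/LB" and cur in ("B", "LB"):
        return "unchanged"
    diff = _RANK[cur] - _RANK[prior]
    if diff > 0:
        return "upgraded"
    if diff < 0:
        return "downgraded"
    return "unchanged"


def reclassification_diff(
    current: pd.DataFrame,
    prior: pd.DataFrame | Mapping[str, str],
) -> tuple[pd.DataFrame, dict]:
    """Compare study classifications against prior calls.

    ``current`` needs columns variant_id / tier; ``prior`` maps variant_id to
    a raw or normalized prior call.  Variants missing from the prior table
    are treated as novel.
    """
    if isinstance(prior, pd.DataFrame):
        col = "prior_call" if "prior_call" in prior.columns else prior.columns[1]
        prior_map = {str(r["variant_id"] if "variant_id" in r else r.iloc[0]): str(r[col])
                     for _, r in prior.iterrows()}
    else:
        prior_map = {str(k): str(v) for k, v in prior.items()}
    rows = []
    for _, r in current.iterrows():
        vid = str(r["variant_id"])
        raw = prior_map.get(vid, "novel")
        cat = raw if raw in PRIOR_CATEGORIES else normalize_prior_call(raw)
        rows.append({
            "variant_id": vid,
            "prior": cat,
            "current": _TIER_SHORT.get(str(r["tier"]), str(r["tier"])),
            "transition": _transition(cat, str(r["tier"])),
        })
    table = pd.DataFrame(rows)
    summary = {k: int((table["transition"] == k).sum())
               for k in ("upgraded", "downgraded", "resolved_from_VUS",
                         "unchanged", "novel_classified")}
    vus_start = table[table["prior"].isin(["VUS", "conflicting"])]
    summary["n_prior_vus_or_conflicting"] = int(len(vus_start))
    summary["n_reclassified_from_vus"] = int(
        (vus_start["transition"] == "resolved_from_VUS").sum()
    )
    if len(vus_start):
        summary["pct_reclassified_from_vus"] = round(
            100.0 * summary["n_reclassified_from_vus"] / len(vus_start)
        )
    return table, summary
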