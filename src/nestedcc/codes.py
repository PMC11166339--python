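"""ICD-10 / treatment / drug code lists and prefix-matching semantics.

Claims diagnoses are ICD-10 strings at 3-4 characters; code lists are sets
of *stems* (prefixes), so a list entry ``K25`` covers ``K25``, ``K250``,
``K252`` and so on. Printed ranges such as "K25-28" are expanded to the
stem set {K25, K26, K27, K28}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2,3}$")

#: Drug classes recognised by the pipeline.
DRUG_CLASSES = (
    "nsaid",
    "rebamipide",
    "ppi",
    "h2ra",
    "misoprostol",
    "other_gastroprotective",
    "anticoagulant",
    "antiplatelet",
    "steroid",
    "bisphosphonate",
    "other",
)

#: The five individually tracked NSAIDs (matching factor D), plus a bucket.
NSAID_TYPES = (
    "loxoprofen",
    "celecoxib",
    "diclofenac",
    "meloxicam",
    "ibuprofen",
    "other_nsaid",
)

#: Drug classes whose initiation censors follow-up.
HIGH_RISK_CLASSES = frozenset(
    {"anticoagulant", "antiplatelet", "steroid", "bisphosphonate"}
)

#: Ulcer treatment / prophylaxis classes (exclusion criteria 6 and 7).
GASTROPROTECTIVE_CLASSES = frozenset(
    {"rebamipide", "ppi", "h2ra", "misoprostol", "other_gastroprotective"}
)


def normalize_icd10(code: str) -> str:
    """Normalise an ICD-10 code: strip dots/whitespace, uppercase.

    >>> normalize_icd10("k25.0")
    'K250'
    """
    return code.replace(".", "").replace(" ", "").upper()


def is_valid_icd10(code: str) -> bool:
    """True for a normalised 3-4 character letter+digits ICD-10 code."""
    return bool(_ICD10_RE.match(code))


def code_matches(code: str, prefix_set: Iterable[str]) -> bool:
    """True iff ``code`` equals or extends any stem in ``prefix_set``.

    ``code`` must already be normalised. Matching is reflexive (a stem
    matches itself) and monotone under extension.
    """
    return any(code.startswith(stem) for stem in prefix_set)


@dataclass(frozen=True)
class CodeLists:
    """Named code sets driving cohort entry, exclusions and outcomes.

    The defaults implement the study design for NSAID users with
    osteoarthritis / back pain and an upper-GI-bleeding outcome; every
    set is configurable via YAML (:func:`load_codelists`).
    """

    #: Qualifying indications: osteoarthritis (M16-19) and back pain (M54).
    oa_backpain: frozenset[str] = frozenset({"M16", "M17", "M18", "M19", "M54"})
    #: Prior upper-GI ulcer history (exclusion 3).
    ulcer_history: frozenset[str] = frozenset({"K25", "K26", "K27", "K28", "K922"})
    #: Helicobacter pylori related diagnoses (exclusion 3).
    h_pylori: frozenset[str] = frozenset({"K294", "K296", "A048", "A498", "B980"})
    #: Upper gastrointestinal bleeding (outcome criterion B).
    ugib: frozenset[str] = frozenset(
        {"K250", "K252", "K254", "K256", "K260", "K262", "K264", "K266", "K290", "K922"}
    )
    #: Treatment code for gastroscopy claims.
    gastroscopy: frozenset[str] = frozenset({"160093810"})
    #: Treatment code for hemostatic procedure claims.
    hemostasis: frozenset[str] = frozenset({"150164850"})
    high_risk_drug_classes: frozenset[str] = HIGH_RISK_CLASSES
    gastroprotective_classes: frozenset[str] = GASTROPROTECTIVE_CLASSES
    #: drug_code -> (drug_class, nsaid_type or None)
    drug_map: Mapping[str, tuple[str, str | None]] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_MAP)
    )

    def __post_init__(self) -> None:
        for name in ("oa_backpain", "ulcer_history", "h_pylori", "ugib"):
            for stem in getattr(self, name):
                if not _ICD10_RE.match(stem):
                    raise ValueError(f"{name}: invalid ICD-10 stem {stem!r}")
        for code, (cls, ntype) in self.drug_map.items():
            if cls not in DRUG_CLASSES:
                raise ValueError(f"drug_map[{code!r}]: unknown class {cls!r}")
            if (cls == "nsaid") != (ntype is not None):
                raise ValueError(
                    f"drug_map[{code!r}]: nsaid_type must be present iff class is nsaid"
                )
            if ntype is not None and ntype not in NSAID_TYPES:
                raise ValueError(f"drug_map[{code!r}]: unknown nsaid_type {ntype!r}")

    def classify_drug(self, drug_code: str) -> tuple[str, str | None]:
        """Map a dispensing code to (drug_class, nsaid_type)."""
        return self.drug_map.get(drug_code, ("other", None))


#: Default dispensing-code map: one synthetic-but-plausible code per product
#: covering the five named NSAIDs, rebamipide and the censoring/exclusion
#: classes. Real deployments supply their own map (e.g. ATC-derived).
DEFAULT_DRUG_MAP: dict[str, tuple[str, str | None]] = {
    "LOXOPROFEN60": ("nsaid", "loxoprofen"),
    "CELECOXIB100": ("nsaid", "celecoxib"),
    "DICLOFENAC25": ("nsaid", "diclofenac"),
    "MELOXICAM10": ("nsaid", "meloxicam"),
    "IBUPROFEN200": ("nsaid", "ibuprofen"),
    "NSAID_OTHER": ("nsaid", "other_nsaid"),
    "REBAMIPIDE100": ("rebamipide", None),
    "PPI": ("ppi", None),
    "H2RA": ("h2ra", None),
    "MISOPROSTOL": ("misoprostol", None),
    "GASTRO_OTHER": ("other_gastroprotective", None),
    "WARFARIN": ("anticoagulant", None),
    "ASPIRIN_LD": ("antiplatelet", None),
    "PREDNISOLONE": ("steroid", None),
    "ALENDRONATE": ("bisphosphonate", None),
    "OTHER": ("other", None),
}

#: Milligrams of active ingredient per tablet for the default codes.
DEFAULT_MG_PER_TABLET: dict[str, float] = {
    "LOXOPROFEN60": 60.0,
    "CELECOXIB100": 100.0,
    "DICLOFENAC25": 25.0,
    "MELOXICAM10": 10.0,
    "IBUPROFEN200": 200.0,
    "NSAID_OTHER": 100.0,
    "REBAMIPIDE100": 100.0,
}

#: Reverse lookup: nsaid_type -> default dispensing code.
NSAID_CODE_BY_TYPE: dict[str, str] = {
    ntype: code
    for code, (cls, ntype) in DEFAULT_DRUG_MAP.items()
    if cls == "nsaid" and ntype is not None
}


def load_codelists(path: str) -> CodeLists:
    """Read code lists and the drug map from a YAML config file.

    Keys absent from the file keep their defaults. The drug map is given
    as ``drug_map: {CODE: {class: nsaid, nsaid_type: loxoprofen}, ...}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for name in (
        "oa_backpain",
        "ulcer_history",
        "h_pylori",
        "ugib",
        "gastroscopy",
        "hemostasis",
        "high_risk_drug_classes",
        "gastroprotective_classes",
    ):
        if name in raw:
            vals = raw[name]
            if name in ("oa_backpain", "ulcer_history", "h_pylori", "ugib"):
                vals = [normalize_icd10(str(v)) for v in vals]
            kwargs[name] = frozenset(str(v) for v in vals)
    if "drug_map" in raw:
        dm = {}
        for code, entry in raw["drug_map"].items():
            dm[str(code)] = (entry["class"], entry.get("nsaid_type"))
        kwargs["drug_map"] = dm
    return CodeLists(**kwargs)


def save_codelists(codelists: CodeLists, path: str) -> None:
    """Write code lists to YAML in the shape :func:`load_codelists` reads."""
    out = {
        name: sorted(getattr(codelists, name))
        for name in (
            "oa_backpain",
            "ulcer_history",
            "h_pylori",
            "ugib",
            "gastroscopy",
            "hemostasis",
            "high_risk_drug_classes",
            "gastroprotective_classes",
        )
    }
    out["drug_map"] = {
        code: (
            {"class": cls, "nsaid_type": ntype} if ntype is not None else {"class": cls}
        )
        for code, (cls, ntype) in codelists.drug_map.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
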