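"""Donor/recipient HLA mismatch identification and EMS-3D scoring.

The EMS-3D of a mismatched donor allele is the minimum electrostatic
similarity distance (ESD) between that allele and the relevant set of
recipient alleles: for HLA class I (A, B, C) the donor allele is compared
against all recipient class I alleles (interlocus comparison); for class II
(DRB1, DQ, DP) only against recipient alleles of the same locus
(intralocus comparison).  HLA-DQ and -DP are treated as single
gene products keyed by the beta-chain two-field allele name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .matrix import EsdMatrix

CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DRB1", "DQ", "DP")
LOCI = CLASS_I_LOCI + CLASS_II_LOCI

#: beta-chain gene names folded onto the locus labels used for scoring
_LOCUS_ALIASES = {"DQB1": "DQ", "DPB1": "DP"}

_ALLELE_RE = re.compile(r"^([A-Z0-9]+)\*(\d+):(\d+)([NLSCAQ])?$")


class HlaError(ValueError):
    """Unparseable allele name or invalid typing/comparison."""


@dataclass(frozen=True)
class HlaAllele:
    """A two-field HLA allele, e.g. A*02:01."""

    locus: str
    name: str

    @property
    def hla_class(self) -> str:
        return "I" if self.locus in CLASS_I_LOCI else "II"


def parse_allele(text: str) -> HlaAllele:
    """Parse and normalize an allele name to two-field resolution.

    Accepts an optional ``HLA-`` prefix, folds DQB1/DPB1 onto DQ/DP, is
    case-insensitive and strips expression suffixes (N, L, S, C, A, Q).
    Names not at exactly two-field resolution are rejected, as are loci
    outside A, B, C, DRB1, DQ, DP.
    """
    raw = text.strip().upper()
    if raw.startswith("HLA-"):
        raw = raw[4:]
    m = _ALLELE_RE.match(raw)
    if not m:
        raise HlaError(
            f"cannot parse allele name {text!r}: expected two-field form LOCUS*GG:PP"
        )
    locus = _LOCUS_ALIASES.get(m.group(1), m.group(1))
    if locus not in LOCI:
        raise HlaError(f"unknown HLA locus {m.group(1)!r} in allele {text!r}")
    return HlaAllele(locus, f"{locus}*{m.group(2)}:{m.group(3)}")


@dataclass
class HlaTyping:
    """One subject's HLA typing: up to two alleles per locus.

    Duplicated alleles within a locus mark homozygosity.  Missing loci are
    permitted and listed by :attr:`missing_loci`.
    """

    subject_id: str
    alleles: dict[str, list[HlaAllele]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, allele_list in self.alleles.items():
            if locus not in LOCI:
                raise HlaError(f"unknown locus {locus!r} in typing {self.subject_id!r}")
            if not 1 <= len(allele_list) <= 2:
                raise HlaError(
                    f"typing {self.subject_id!r}: locus {locus} must carry 1-2 alleles"
                )
            for a in allele_list:
                if a.locus != locus:
                    raise HlaError(
                        f"typing {self.subject_id!r}: allele {a.name} filed under locus {locus}"
                    )

    @property
    def missing_loci(self) -> list[str]:
        return [l for l in LOCI if l not in self.alleles]

    def at_locus(self, locus: str) -> list[HlaAllele]:
        return self.alleles.get(locus, [])

    def class_i_alleles(self) -> list[HlaAllele]:
        return [a for locus in CLASS_I_LOCI for a in self.at_locus(locus)]

    @classmethod
    def from_names(cls, subject_id: str, names: Iterable[str]) -> "HlaTyping":
        alleles: dict[str, list[HlaAllele]] = {}
        for name in names:
            a = parse_allele(name)
            alleles.setdefault(a.locus, []).append(a)
        return cls(subject_id, alleles)


def read_typings(path: str | Path) -> dict[str, HlaTyping]:
    """Read typings from CSV with columns subject_id, locus, allele_1, allele_2."""
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "locus", "allele_1"}
    if not required.issubset(df.columns):
        raise HlaError(f"typing CSV must have columns {sorted(required)}")
    typings: dict[str, HlaTyping] = {}
    grouped: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        names = [row["allele_1"]]
        if "allele_2" in df.columns and isinstance(row.get("allele_2"), str):
            names.append(row["allele_2"])
        grouped.setdefault(row["subject_id"], []).extend(names)
    for sid, names in grouped.items():
        typings[sid] = HlaTyping.from_names(sid, names)
    return typings


@dataclass
class MismatchRecord:
    """One donor mismatch: its comparator ESDs and the minimum (EMS-3D)."""

    donor_allele: HlaAllele
    comparators: list[HlaAllele]
    esds: list[float]
    ems3d: float
    mode: str  # "interlocus" | "intralocus"


EsdLookup = Callable[[str, str], float]


def as_esd_lookup(source: EsdMatrix | Mapping | EsdLookup) -> EsdLookup:
    """Adapt an EsdMatrix, a {(a, b): esd} mapping, or a callable to a lookup."""
    if isinstance(source, EsdMatrix):
        return source.lookup
    if callable(source) and not isinstance(source, Mapping):
        return source

    def lookup(a: str, b: str) -> float:
        for key in ((a, b), (b, a)):
            if key in source:
                return float(source[key])
        raise KeyError(f"no ESD entry for pair ({a}, {b})")

    return lookup


def find_mismatches(donor: HlaTyping, recipient: HlaTyping) -> list[HlaAllele]:
    """Donor alleles absent from the recipient's typing at the same locus.

    A homozygous donor mismatch appears once (only one observation enters
    downstream models).
    """
    mismatches: list[HlaAllele] = []
    for locus, donor_alleles in donor.alleles.items():
        recipient_names = {a.name for a in recipient.at_locus(locus)}
        seen: set[str] = set()
        for a in donor_alleles:
            if a.name not in recipient_names and a.name not in seen:
                mismatches.append(a)
                seen.add(a.name)
    return mismatches


def ems3d_for_mismatch(
    mismatch: HlaAllele,
    recipient: HlaTyping,
    esd_lookup: EsdMatrix | Mapping | EsdLookup,
) -> MismatchRecord:
    """EMS-3D of one donor mismatch against the recipient's alleles.

    Class I mismatches are compared against every recipient class I allele
    (interlocus); class II mismatches only against recipient alleles of the
    same locus (intralocus).  The EMS-3D is the minimum comparator ESD.
    """
    lookup = as_esd_lookup(esd_lookup)
    if mismatch.hla_class == "I":
        comparators = recipient.class_i_alleles()
        mode = "interlocus"
        if not comparators:
            raise HlaError(
                f"recipient {recipient.subject_id!r} has no class I alleles to "
                f"compare against {mismatch.name}"
            )
    else:
        comparators = recipient.at_locus(mismatch.locus)
        mode = "intralocus"
        if not comparators:
            raise HlaError(
                f"recipient {recipient.subject_id!r} has no {mismatch.locus} alleles; "
                f"intralocus comparison for {mismatch.name} is undefined"
            )
    esds: list[float] = []
    for comp in comparators:
        try:
            esds.append(float(lookup(mismatch.name, comp.name)))
        except KeyError as exc:
            raise HlaError(
                f"missing ESD for pair ({mismatch.name}, {comp.name})"
            ) from exc
    return MismatchRecord(mismatch, list(comparators), esds, min(esds), mode)


def score_pair(
    donor: HlaTyping,
    recipient: HlaTyping,
    esd_lookup: EsdMatrix | Mapping | EsdLookup,
) -> list[MismatchRecord]:
    """All mismatch records for one donor-recipient pair."""
    return [
        ems3d_for_mismatch(m, recipient, esd_lookup)
        for m in find_mismatches(donor, recipient)
    ]


def locus_total(records: Sequence[MismatchRecord], locus: str) -> float:
    """Sum of EMS-3D over a pair's mismatches at one locus (0 if none)."""
    return float(sum(r.ems3d for r in records if r.donor_allele.locus == locus))


def records_to_frame(
    records: Sequence[MismatchRecord], donor_id: str = "", recipient_id: str = ""
) -> pd.DataFrame:
    """Mismatch records as the canonical output table."""
    return pd.DataFrame(
        {
            "donor_id": donor_id,
            "recipient_id": recipient_id,
            "locus": [r.donor_allele.locus for r in records],
            "donor_allele": [r.donor_allele.name for r in records],
            "ems3d": [r.ems3d for r in records],
            "mode": [r.mode for r in records],
        }
    )
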