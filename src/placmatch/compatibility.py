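"""Mare-foal MHC compatibility classification from microsatellite alleles.

Each mare-foal pair is classified separately for MHC class I and class II
into one of four mutually exclusive categories, based on set containment of
the distinct alleles at every locus of the class:

* ``MC`` (mare compatibility) — at every locus the foal carries no allele
  absent from the mare (foal's allele set ⊆ mare's), but not vice versa at
  every locus: the mare's immune system would see nothing foreign.
* ``FC`` (foal compatibility) — the mirror image (mare's set ⊆ foal's at
  every locus).
* ``MFC`` — both containments hold at every locus (identical allele sets).
* ``NC`` — none of the three patterns holds at every locus of the class.

Containment is on distinct-allele *sets*, not multisets: a mare {a,b}
contains a foal homozygous {a,a}, since the criterion is presence/absence
of foreign alleles. Null alleles are invisible here (a null-masked
homozygote is taken at face value); the popgen_qc module reports per-locus
null-allele frequencies as the corresponding caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import UndeterminedPairError, ValidationError
from .genotype_io import Call, GenotypeTable, LocusPanel, PairRecord, default_panel

__all__ = [
    "CATEGORIES",
    "LocusCompatibility",
    "ClassCompatibilityCall",
    "locus_flags",
    "category_from_flags",
    "classify_pair",
    "classify_pairs",
    "tabulate_compatibility",
]

CATEGORIES = ("MC", "FC", "MFC", "NC")


@dataclass(frozen=True)
class LocusCompatibility:
    """Containment flags for one locus of a mare-foal pair."""

    locus: str
    foal_in_mare: bool | None
    mare_in_foal: bool | None
    testable: bool


@dataclass(frozen=True)
class ClassCompatibilityCall:
    """Compatibility category of one pair within one MHC class."""

    mare_id: str
    foal_id: str
    mhc_class: str
    category: str
    loci_used: int


def locus_flags(mare_call: Call | None, foal_call: Call | None, locus: str = "") -> LocusCompatibility:
    """Compute both containment flags at one locus; missing on either side → untestable."""
    if mare_call is None or foal_call is None:
        return LocusCompatibility(locus, None, None, False)
    mare_set, foal_set = set(mare_call), set(foal_call)
    return LocusCompatibility(
        locus,
        foal_in_mare=foal_set <= mare_set,
        mare_in_foal=mare_set <= foal_set,
        testable=True,
    )


def category_from_flags(flags: Sequence[tuple[bool, bool]]) -> str:
    """Aggregate per-locus (foal_in_mare, mare_in_foal) flags into a category.

    A pattern must hold at *all* loci to qualify; pairs satisfying both
    containments everywhere are MFC only (MC and FC are reported exclusively
    of MFC, so the four categories partition the pairs).
    """
    if not flags:
        raise ValidationError("no testable loci to aggregate")
    all_fim = all(f for f, _ in flags)
    all_mif = all(m for _, m in flags)
    if all_fim and all_mif:
        return "MFC"
    if all_fim:
        return "MC"
    if all_mif:
        return "FC"
    return "NC"


def classify_pair(
    mare_id: str,
    foal_id: str,
    table: GenotypeTable,
    panel: LocusPanel | None = None,
    mhc_class: str = "I",
    missing_policy: str = "ignore",
) -> ClassCompatibilityCall:
    """Classify one mare-foal pair within one MHC class.

    ``missing_policy="ignore"`` (default) classifies on the testable loci and
    records how many were used; ``"strict"`` refuses pairs with any
    untestable locus in the class.
    """
    panel = panel or default_panel()
    if mhc_class not in ("I", "II"):
        raise ValidationError(f"mhc_class must be 'I' or 'II', got {mhc_class!r}")
    if missing_policy not in ("ignore", "strict"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    loci = panel.class_loci(mhc_class)
    flags: list[tuple[bool, bool]] = []
    untestable = 0
    for locus in loci:
        lc = locus_flags(table.get(mare_id, locus), table.get(foal_id, locus), locus)
        if lc.testable:
            flags.append((lc.foal_in_mare, lc.mare_in_foal))
        else:
            untestable += 1
    if not flags or (missing_policy == "strict" and untestable):
        raise UndeterminedPairError(
            f"pair ({mare_id}, {foal_id}): {untestable} untestable "
            f"locus/loci in MHC class {mhc_class}"
        )
    return ClassCompatibilityCall(mare_id, foal_id, mhc_class, category_from_flags(flags), len(flags))


def classify_pairs(
    table: GenotypeTable,
    pairs: Sequence[PairRecord],
    panel: LocusPanel | None = None,
    missing_policy: str = "ignore",
) -> pd.DataFrame:
    """Classify every pair for both MHC classes.

    Returns a tidy frame with one row per (pair, class): columns mare_id,
    foal_id, rfm, group, mhc_class, category, loci_used.
    """
    rows = []
    for pair in pairs:
        for mhc_class in ("I", "II"):
            call = classify_pair(pair.mare_id, pair.foal_id, table, panel, mhc_class,
                                 missing_policy)
            rows.append(
                {
                    "mare_id": pair.mare_id,
                    "foal_id": pair.foal_id,
                    "rfm": pair.rfm,
                    "group": pair.group,
                    "mhc_class": mhc_class,
                    "category": call.category,
                    "loci_used": call.loci_used,
                }
            )
    return pd.DataFrame(rows)


def tabulate_compatibility(pairs: Sequence[PairRecord], calls: pd.DataFrame) -> pd.DataFrame:
    """Counts (and integer percentages) per group x MHC class x category.

    Rows are indexed (group, mhc_class); ``n_<cat>`` columns partition each
    group so that their sum equals the group size; ``pct_<cat>`` columns are
    percentages rounded to integers.
    """
    by_pair = {(r.mare_id, r.foal_id) for r in pairs}
    have = {(m, f, c) for m, f, c in zip(calls["mare_id"], calls["foal_id"], calls["mhc_class"])}
    for mare, foal in by_pair:
        for mhc_class in ("I", "II"):
            if (mare, foal, mhc_class) not in have:
                warnings.warn(
                    f"pair ({mare}, {foal}) has no MHC {mhc_class} call; excluded from that row",
                    stacklevel=2,
                )
    rows = []
    for group in ("RFM", "control"):
        for mhc_class in ("I", "II"):
            sub = calls[(calls["group"] == group) & (calls["mhc_class"] == mhc_class)]
            n = len(sub)
            record: dict[str, object] = {"group": group, "mhc_class": mhc_class, "n": n}
            for cat in CATEGORIES:
                count = int((sub["category"] == cat).sum())
                record[f"n_{cat}"] = count
                record[f"pct_{cat}"] = int(round(100 * count / n)) if n else 0
            rows.append(record)
    return pd.DataFrame(rows).set_index(["group", "mhc_class"])
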