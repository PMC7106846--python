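"""Plant taxonomic classification into 13 mutually exclusive categories.

Every Viridiplantae lineage maps to exactly one of: lamiids, asterids other
than lamiids, malvids, fabids, eudicots other than rosids and asterids,
commelinids, monocots other than commelinids, angiosperms other than
eudicots and monocots, gymnosperms, Polypodiopsida, Embryophyta other than
Euphyllophyta, Streptophyta other than Embryophyta, and Viridiplantae other
than Streptophyta.  Matching is most-specific-first over NCBI-style clade
names, with the NCBI synonyms honoured (eudicots = eudicotyledons,
Angiospermae = Magnoliophyta, Gymnospermae = Acrogymnospermae); the
"other than" buckets are assigned only when no subordinate category matched.
A lineage containing the unranked "rosids" but neither fabids nor malvids
falls to the eudicots bucket.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "TaxCategory",
    "Lineage",
    "ConservationProfile",
    "category_of",
    "conservation_profile",
    "read_lineage_table",
    "write_lineage_table",
]


class TaxCategory(str, enum.Enum):
    LAMIIDS = "lamiids"
    ASTERIDS_OTHER = "asterids_other"
    MALVIDS = "malvids"
    FABIDS = "fabids"
    EUDICOTS_OTHER = "eudicots_other"
    COMMELINIDS = "commelinids"
    MONOCOTS_OTHER = "monocots_other"
    ANGIOSPERMS_OTHER = "angiosperms_other"
    GYMNOSPERMS = "gymnosperms"
    POLYPODIOPSIDA = "polypodiopsida"
    EMBRYOPHYTA_OTHER = "embryophyta_other"
    STREPTOPHYTA_OTHER = "streptophyta_other"
    VIRIDIPLANTAE_OTHER = "viridiplantae_other"


@dataclass(frozen=True)
class Lineage:
    """Root-to-species clade names for one species, plus its order."""

    species_id: str
    clade_names: tuple[str, ...]
    order_name: str
    seq_total: int | None = None  # declared EST/TSA/curated sequence count

    def __post_init__(self):
        if not self.clade_names:
            raise ValueError(f"{self.species_id}: empty lineage")


# (category, matching clade-name synonyms) in most-specific-first order
_RULES: tuple[tuple[TaxCategory, frozenset[str]], ...] = (
    (TaxCategory.LAMIIDS, frozenset({"lamiids"})),
    (TaxCategory.ASTERIDS_OTHER, frozenset({"asterids"})),
    (TaxCategory.MALVIDS, frozenset({"malvids"})),
    (TaxCategory.FABIDS, frozenset({"fabids"})),
    (TaxCategory.EUDICOTS_OTHER, frozenset({"eudicotyledons", "eudicots"})),
    (TaxCategory.COMMELINIDS, frozenset({"commelinids"})),
    (TaxCategory.MONOCOTS_OTHER, frozenset({"liliopsida", "monocots"})),
    (TaxCategory.ANGIOSPERMS_OTHER, frozenset({"magnoliophyta", "angiospermae"})),
    (TaxCategory.GYMNOSPERMS, frozenset({"acrogymnospermae", "gymnospermae"})),
    (TaxCategory.POLYPODIOPSIDA, frozenset({"polypodiopsida"})),
    (TaxCategory.EMBRYOPHYTA_OTHER, frozenset({"embryophyta"})),
    (TaxCategory.STREPTOPHYTA_OTHER, frozenset({"streptophyta"})),
    (TaxCategory.VIRIDIPLANTAE_OTHER, frozenset({"viridiplantae"})),
)


def category_of(lineage: Lineage) -> TaxCategory:
    """Map a Viridiplantae lineage to its single taxonomic category."""
    names = {n.casefold() for n in lineage.clade_names}
    if "viridiplantae" not in names:
        raise ValueError(
            f"{lineage.species_id}: lineage is outside Viridiplantae"
        )
    for category, synonyms in _RULES:
        if names & synonyms:
            return category
    raise AssertionError("unreachable: Viridiplantae rule is total")


@dataclass
class ConservationProfile:
    """Per-category order counts for one candidate's representatives.

    ``per_category`` counts representative orders only, so its values sum to
    the number of representatives; the query species' own category is kept
    separately because it is present by construction even without a hit.
    """

    candidate_id: str
    per_category: dict[TaxCategory, int]
    original_category: TaxCategory | None = None


def conservation_profile(
    candidate_id: str,
    reps,
    lineages: dict[str, Lineage],
    original_species: str | None = None,
) -> ConservationProfile:
    """Classify each representative order's species; count per category."""
    counts: dict[TaxCategory, int] = {}
    for order in sorted(reps.per_order):
        rep = reps.per_order[order]
        cat = category_of(lineages[rep.species_id])
        counts[cat] = counts.get(cat, 0) + 1
    original_cat = None
    if original_species is not None:
        original_cat = category_of(lineages[original_species])
    return ConservationProfile(candidate_id, counts, original_cat)


def read_lineage_table(path: str | Path) -> dict[str, Lineage]:
    """Read the lineage TSV: species_id, order_name, ';'-joined clades
    [, declared sequence total]."""
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("species_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}: line {ln}: expected 3 or 4 columns")
            total = int(parts[3]) if len(parts) == 4 and parts[3] else None
            out[parts[0]] = Lineage(
                species_id=parts[0],
                clade_names=tuple(parts[2].split(";")),
                order_name=parts[1],
                seq_total=total,
            )
    return out


def write_lineage_table(lineages: dict[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\torder_name\tclade_names\tseq_total\n")
        for sp in sorted(lineages):
            l = lineages[sp]
            total = "" if l.seq_total is None else str(l.seq_total)
            fh.write(f"{l.species_id}\t{l.order_name}\t{';'.join(l.clade_names)}\t{total}\n")
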