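"""Divergence-time proxies for paralogous pairs.

Two monotone proxies of time since duplication are attached to each adjacent
paralog pair: ``d_S`` (synonymous substitutions per synonymous site, supplied
in the paralog table — estimated externally, e.g. by PAML) and ``T_phy`` (the
ordinal phylogenetic age of the duplication, derived from the annotated most
recent common ancestor).  Smaller values mean a more recent duplication.

The default ancestor -> rank ladder shipped with the package is the standard
Ensembl human ancestor ladder (Homo sapiens ... Opisthokonta).  It is a
synthetic stand-in for any study-specific table and can be overridden with a
two-column config file.  d_S values above a saturation cap (default 10, the
usual PAML saturation convention) are flagged and excluded from rank
correlations by default.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING

from .genome_io import ParalogTable, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .pairing import AdjacentPair

__all__ = ["AgeMap", "assign_tphy", "attach_ds", "DS_SATURATION_CAP"]

DS_SATURATION_CAP = 10.0


class AgeMap:
    """Ordered ancestor-taxon -> ordinal-age mapping (0 = most recent)."""

    def __init__(self, ranks: dict[str, int]):
        if len(set(ranks.values())) != len(ranks):
            raise ValidationError("age ranks must be unique")
        if any(r < 0 for r in ranks.values()):
            raise ValidationError("age ranks must be non-negative")
        self.ranks = dict(ranks)

    def __contains__(self, label: str) -> bool:
        return label in self.ranks

    def __getitem__(self, label: str) -> int:
        return self.ranks[label]

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in sorted(self.ranks.items(), key=lambda kv: kv[1])]

    @classmethod
    def from_file(cls, path: str | Path) -> "AgeMap":
        ranks: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("ancestor\t"):
                    continue
                label, rank = line.split("\t")
                ranks[label] = int(rank)
        return cls(ranks)

    @classmethod
    def default(cls) -> "AgeMap":
        """The shipped Ensembl-ladder stand-in map."""
        ref = resources.files("ctcf_divergence.data") / "age_map.tsv"
        with resources.as_file(ref) as path:
            return cls.from_file(path)


def assign_tphy(pair: "AdjacentPair", paralog_table: ParalogTable,
                age_map: AgeMap) -> float:
    """Ordinal phylogenetic age of a paralog pair; NaN if the label is unmapped."""
    if pair.relation != "paralog":
        raise ValueError(f"{pair.pair_id}: T_phy is defined for paralog pairs only")
    entry = paralog_table.lookup(pair.left.gene_id, pair.right.gene_id)
    if entry is None:
        raise ValueError(f"{pair.pair_id}: pair absent from paralog table")
    _, ancestor = entry
    if ancestor not in age_map:
        return math.nan
    return float(age_map[ancestor])


def attach_ds(pair: "AdjacentPair", paralog_table: ParalogTable,
              saturation_cap: float = DS_SATURATION_CAP,
              ) -> tuple[float, bool]:
    """(d_S, saturated) for a paralog pair; d_S is NaN when absent.

    Saturated values (d_S > cap) are returned with the flag set so callers can
    exclude them from rank correlations while keeping the pair for T_phy.
    """
    if pair.relation != "paralog":
        raise ValueError(f"{pair.pair_id}: d_S is defined for paralog pairs only")
    entry = paralog_table.lookup(pair.left.gene_id, pair.right.gene_id)
    if entry is None:
        raise ValueError(f"{pair.pair_id}: pair absent from paralog table")
    ds, _ = entry
    if ds is None or (isinstance(ds, float) and math.isnan(ds)):
        return math.nan, False
    if ds < 0:
        raise ValidationError(f"{pair.pair_id}: negative d_S {ds}")
    return float(ds), ds > saturation_cap
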