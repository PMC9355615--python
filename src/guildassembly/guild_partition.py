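"""Partition an OTU table into trophic-guild sub-tables.

Classification rules:

* only ``Highly Probable`` / ``Probable`` confidence is accepted;
* a trophic mode containing the ``-`` separator (multiple modes) is excluded;
* any guild mentioning endophytes is excluded;
* mycorrhizal = guild contains "arbuscular mycorrhizal" or "ectomycorrhizal"
  (matched case-insensitively on the guild string, not the mode);
* saprotrophic / pathotrophic = single trophic mode Saprotroph / Pathotroph.

OTUs not meeting any rule stay in the total table but join no guild.
"""

from __future__ import annotations

import warnings
from typing import Mapping

from .errors import DegenerateStatisticError
from .tabular_io import GuildAnnotation, GuildRecord, OtuTable

__all__ = ["GUILDS", "classify_otu", "partition_table", "guild_summary"]

GUILDS = ("mycorrhizal", "saprotrophic", "pathotrophic")

_ACCEPTED_CONFIDENCE = frozenset({"Highly Probable", "Probable"})
_MODE_SEPARATOR = "-"


def classify_otu(record: GuildRecord) -> str:
    """Return 'mycorrhizal', 'saprotrophic', 'pathotrophic' or 'excluded'."""
    if record.confidence not in _ACCEPTED_CONFIDENCE:
        return "excluded"
    mode = record.trophic_mode.strip()
    if _MODE_SEPARATOR in mode:
        return "excluded"
    guild = record.guild.lower()
    if "endophyte" in guild:
        return "excluded"
    if "arbuscular mycorrhizal" in guild or "ectomycorrhizal" in guild:
        return "mycorrhizal"
    mode_lower = mode.lower()
    if mode_lower == "saprotroph":
        return "saprotrophic"
    if mode_lower == "pathotroph":
        return "pathotrophic"
    return "excluded"


def partition_table(table: OtuTable, annotation: GuildAnnotation
                    ) -> dict[str, OtuTable]:
    """Split ``table`` into total plus the three guild sub-tables.

    OTUs absent from the annotation count as unassigned. Annotation records
    for OTUs missing from the table raise a warning, not an error.
    """
    by_otu = annotation.by_otu()
    table_otus = set(table.otu_ids)
    stray = [o for o in by_otu if o not in table_otus]
    if stray:
        warnings.warn(
            f"annotation references {len(stray)} OTU(s) absent from the table "
            f"(e.g. {stray[0]!r})", stacklevel=2)
    members: dict[str, list[str]] = {g: [] for g in GUILDS}
    for otu in table.otu_ids:
        record = by_otu.get(otu)
        if record is None:
            continue
        cls = classify_otu(record)
        if cls in members:
            members[cls].append(otu)
    out: dict[str, OtuTable] = {"total": table}
    for g in GUILDS:
        out[g] = table.select_otus(members[g])
    return out


def guild_summary(partition: Mapping[str, OtuTable]) -> dict[str, dict]:
    """Per-guild OTU count and fraction of total sequences."""
    total = partition["total"]
    total_sum = int(total.counts.sum())
    if total_sum == 0:
        raise DegenerateStatisticError(
            "total table has zero sequences; fractions undefined")
    summary: dict[str, dict] = {}
    for name, sub in partition.items():
        seq = int(sub.counts.sum())
        summary[name] = {
            "n_otus": sub.n_otus,
            "n_sequences": seq,
            "fraction_of_total": seq / total_sum,
        }
    return summary
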