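"""Gene and miRNA name normalization for curated literature pairs.

Curated miRNA--mRNA pair lists mix official gene symbols with aliases, and
mature miRNA names with precursor names and legacy capitalizations
("mir-137", "miR137").  This module resolves both sides deterministically:
gene aliases through a single-hop alias table, miRNA names through a map
harvested from a miRBase-dialect mature FASTA.  A precursor name expands to
all of its mature products (-5p/-3p); arm choice is a configurable policy.
Unresolvable names are carried with an explicit ``UNRESOLVED`` marker,
never silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

UNRESOLVED = "UNRESOLVED"

_ARM_SUFFIXES = ("-5p", "-3p")


@dataclass(frozen=True)
class PairRecord:
    """One curated miRNA--target-gene pair, names exactly as published."""

    mirna_name_raw: str
    gene_name_raw: str
    source: str = ""

    def __post_init__(self):
        if not self.mirna_name_raw or not self.gene_name_raw:
            raise ValueError("pair names must be non-empty")


@dataclass(frozen=True)
class ResolvedPair:
    """A pair after normalization; unresolved sides carry the marker."""

    pair: PairRecord
    mature_mirnas: tuple[str, ...]  # empty iff the miRNA side is unresolved
    gene_symbol: str                # UNRESOLVED iff the gene side failed
    gene_id: str | None

    @property
    def resolved(self) -> bool:
        return bool(self.mature_mirnas) and self.gene_symbol != UNRESOLVED


class AliasTable:
    """Case-insensitive single-hop alias -> official gene symbol mapping.

    Multi-hop tables (an official symbol that is itself an alias of a
    different symbol) are rejected at construction to rule out chains and
    cycles.
    """

    def __init__(self, alias_to_official: Mapping[str, str],
                 official_to_id: Mapping[str, str]):
        self._alias = {a.upper(): o for a, o in alias_to_official.items()}
        self._ids = dict(official_to_id)
        self._official_upper = {o.upper(): o for o in self._ids}
        for alias, official in self._alias.items():
            if official not in self._ids:
                raise ValueError(f"official symbol {official!r} has no stable "
                                 "gene ID")
            target = self._alias.get(official.upper())
            if target is not None and target != official:
                raise ValueError(
                    f"multi-hop alias chain: {alias!r} -> {official!r} -> "
                    f"{target!r}")

    def lookup(self, raw_name: str) -> tuple[str, str | None]:
        """Resolve a raw gene name to (official symbol, stable gene ID)."""
        key = raw_name.strip().upper()
        if key in self._official_upper:
            official = self._official_upper[key]
            return official, self._ids[official]
        if key in self._alias:
            official = self._alias[key]
            return official, self._ids[official]
        return UNRESOLVED, None


def load_alias_table(path: str | Path) -> AliasTable:
    """Load an alias TSV with columns ``alias``, ``official``, ``gene_id``.

    Official symbols should appear as identity rows so that every official
    name has a stable ID.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"alias", "official", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"alias table {path} needs columns {sorted(required)}")
    alias_to_official: dict[str, str] = {}
    official_to_id: dict[str, str] = {}
    for r in df.itertuples(index=False):
        official_to_id.setdefault(r.official, r.gene_id)
        if official_to_id[r.official] != r.gene_id:
            raise ValueError(f"official symbol {r.official!r} maps to two "
                             "stable IDs")
        if str(r.alias).upper() != str(r.official).upper():
            alias_to_official[r.alias] = r.official
    return AliasTable(alias_to_official, official_to_id)


def normalize_gene(raw_name: str, alias_table: AliasTable
                   ) -> tuple[str, str | None]:
    """Resolve a curated gene name; official symbols pass through unchanged."""
    symbol, gene_id = alias_table.lookup(raw_name)
    if symbol == UNRESOLVED:
        log.warning("gene name %r could not be resolved", raw_name)
    return symbol, gene_id


def _squash(name: str) -> str:
    """Fold a miRNA name for tolerant matching (case, hyphens, species)."""
    s = re.sub(r"[^0-9a-z]", "", name.lower())
    return s if s.startswith("hsa") else "hsa" + s


def _precursor_of(mature_name: str) -> str:
    base = mature_name
    for suffix in _ARM_SUFFIXES:
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    return base.replace("miR", "mir")


class MiRNANameMap:
    """Canonical mature miRNA names plus precursor and legacy lookups.

    Built from a mature FASTA: every canonical mature name therefore has a
    sequence.  Precursor names ("hsa-mir-137") expand to all mature
    products; legacy spellings match through a folded form that ignores
    case, hyphens and a missing species prefix (defaulting to ``hsa-`` as
    the study organism is human).
    """

    def __init__(self, mature_names: Iterable[str],
                 legacy: Mapping[str, str] | None = None):
        self.mature_names = list(mature_names)
        canonical = set(self.mature_names)
        self.precursor_to_matures: dict[str, list[str]] = {}
        for name in self.mature_names:
            self.precursor_to_matures.setdefault(_precursor_of(name),
                                                 []).append(name)
        self._folded: dict[str, tuple[str, ...]] = {}
        for name in self.mature_names:
            self._register(_squash(name), (name,))
        for prec, matures in self.precursor_to_matures.items():
            self._register(_squash(prec), tuple(matures))
        for legacy_name, target in (legacy or {}).items():
            if target not in canonical:
                raise ValueError(f"legacy target {target!r} has no sequence "
                                 "in the mature FASTA")
            self._folded[_squash(legacy_name)] = (target,)

    def _register(self, key: str, names: tuple[str, ...]) -> None:
        existing = self._folded.get(key)
        if existing is not None and set(existing) != set(names):
            merged = tuple(dict.fromkeys(existing + names))
            log.warning("ambiguous folded miRNA name %r; keeping union %s",
                        key, merged)
            self._folded[key] = merged
        else:
            self._folded[key] = names

    def resolve(self, raw_name: str) -> tuple[str, ...]:
        return self._folded.get(_squash(raw_name.strip()), ())


def build_mirna_name_map(mirna_sequences: Mapping[str, str],
                         legacy: Mapping[str, str] | None = None
                         ) -> MiRNANameMap:
    """Harvest a name map from {mature name: sequence} (see read_mirna_fasta)."""
    return MiRNANameMap(mirna_sequences.keys(), legacy=legacy)


def normalize_mirna(raw_name: str, name_map: MiRNANameMap,
                    arm_policy: str = "both") -> list[str]:
    """Resolve a curated miRNA name to canonical mature name(s).

    Precursor names expand to all mature products; ``arm_policy`` then
    selects "both" (default), "5p" or "3p".  Unknown names return an empty
    list (the unresolved case) with a logged warning.
    """
    if arm_policy not in ("both", "5p", "3p"):
        raise ValueError(f"unknown arm policy {arm_policy!r}")
    names = list(name_map.resolve(raw_name))
    if not names:
        log.warning("miRNA name %r could not be resolved", raw_name)
        return []
    if arm_policy != "both" and len(names) > 1:
        preferred = [n for n in names if n.endswith(f"-{arm_policy}")]
        names = preferred or names
    return names


def read_pairs(path: str | Path) -> list[PairRecord]:
    """Read a curated pairs TSV with columns ``mirna``, ``gene`` (+ ``source``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"mirna", "gene"} <= set(df.columns):
        raise ValueError(f"pairs table {path} needs 'mirna' and 'gene' columns")
    has_source = "source" in df.columns
    return [PairRecord(mirna_name_raw=r.mirna, gene_name_raw=r.gene,
                       source=(r.source if has_source else "") or "")
            for r in df.itertuples(index=False)]


def resolve_pairs(pairs: Sequence[PairRecord], alias_table: AliasTable,
                  name_map: MiRNANameMap, arm_policy: str = "both"
                  ) -> list[ResolvedPair]:
    """Normalize every curated pair; input count equals output count."""
    out = []
    for p in pairs:
        symbol, gene_id = normalize_gene(p.gene_name_raw, alias_table)
        matures = tuple(normalize_mirna(p.mirna_name_raw, name_map,
                                        arm_policy=arm_policy))
        out.append(ResolvedPair(pair=p, mature_mirnas=matures,
                                gene_symbol=symbol, gene_id=gene_id))
    return out
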