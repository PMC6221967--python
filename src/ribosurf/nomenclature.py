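"""Linking ribosomal-protein gene symbols to structure-file chain naming.

Structure depositions name their polymer entities with free text ("60S
ribosomal protein L4"), with the unified universal names (uL4, eS6, ...), or
both, while expression data speaks in gene symbols (Rpl4, Rps6).  This module
bundles a three-way table for the ~80 mouse cytoplasmic ribosomal proteins
and resolves a gene symbol to the chain(s) of a loaded structure through a
strict matching cascade:

1. the universal name as a standalone token of the entity description;
2. a legacy protein name as a contiguous token run of the description;
3. the ``L<number>``/``S<number>`` token extracted from the gene symbol
   matched against "ribosomal protein L<n>/S<n>" descriptions with exact
   number equality (so Rpl4 never matches L40).

The first stage that hits wins; an unmatched gene yields an empty map rather
than an error (mitochondrial Mrpl/Mrps genes on a cytoplasmic structure are
the expected such case).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import ConsistencyError, TableError
from .exposure import ChainExposure
from .structure_io import Structure

MatchRoute = Literal["universal_name", "legacy_name", "entity_description", "manual"]
GeneLabel = Literal["surface", "internal", "unmapped"]


@dataclass(frozen=True)
class RpRecord:
    gene_symbol: str
    universal_name: str
    legacy_names: tuple[str, ...]
    subunit: Literal["large", "small"]


@dataclass
class GeneChainMap:
    gene_symbol: str
    matched_chain_ids: list[str] = field(default_factory=list)
    match_route: MatchRoute = "entity_description"
    confidence: Literal["exact", "fuzzy"] = "exact"


def _normalize(text: str) -> str:
    text = re.sub(r"[^\w\s]", " ", text.casefold())
    return re.sub(r"\s+", " ", text).strip()


def _tokens(text: str) -> list[str]:
    return _normalize(text).split()


# ---------------------------------------------------------------------------
# table loading
# ---------------------------------------------------------------------------

def _parse_rows(lines: Iterable[str], source: str) -> list[RpRecord]:
    records = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if lineno == 1 and line.lower().startswith("gene_symbol"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise TableError(f"{source}:{lineno}: expected 4 tab-separated columns")
        gene, universal, legacy, subunit = (p.strip() for p in parts)
        if not gene or not universal or subunit not in ("large", "small"):
            raise TableError(f"{source}:{lineno}: malformed record")
        prefix = gene.casefold()
        if prefix.startswith("rpl") and subunit != "large":
            raise TableError(f"{source}:{lineno}: {gene} marked {subunit}")
        if prefix.startswith("rps") and subunit != "small":
            raise TableError(f"{source}:{lineno}: {gene} marked {subunit}")
        records.append(RpRecord(
            gene_symbol=gene,
            universal_name=universal,
            legacy_names=tuple(n.strip() for n in legacy.split(";") if n.strip()),
            subunit=subunit,  # type: ignore[arg-type]
        ))
    return records


def load_rp_table(path: str | Path | None = None) -> list[RpRecord]:
    """Bundled mouse cytoplasmic RP table, optionally extended by a TSV file.

    The override TSV carries the four record columns (legacy names
    semicolon-joined) and is appended to the bundled table; any duplicated
    gene symbol or universal name is an error.
    """
    text = resources.files("ribosurf").joinpath("data/rp_table.tsv").read_text()
    records = _parse_rows(text.splitlines(), "rp_table.tsv")
    if path is not None:
        records += _parse_rows(Path(path).read_text().splitlines(), str(path))
    seen_genes: set[str] = set()
    seen_universal: set[str] = set()
    for rec in records:
        g, u = rec.gene_symbol.casefold(), rec.universal_name.casefold()
        if g in seen_genes:
            raise TableError(f"duplicate gene_symbol {rec.gene_symbol!r}")
        if u in seen_universal:
            raise TableError(f"duplicate universal_name {rec.universal_name!r}")
        seen_genes.add(g)
        seen_universal.add(u)
    return records


def find_record(gene: str, table: Sequence[RpRecord]) -> RpRecord | None:
    key = gene.strip().casefold()
    for rec in table:
        if rec.gene_symbol.casefold() == key:
            return rec
    return None


# ---------------------------------------------------------------------------
# gene -> chain resolution
# ---------------------------------------------------------------------------

_GENE_NUMBER_RE = re.compile(r"^rp([ls])(\d+[a-z]*\d*)$", re.IGNORECASE)


def _contains_token_run(haystack: list[str], needle: list[str]) -> bool:
    if not needle or len(needle) > len(haystack):
        return False
    return any(
        haystack[i:i + len(needle)] == needle
        for i in range(len(haystack) - len(needle) + 1)
    )


def resolve_gene(
    gene: str, structure: Structure, table: Sequence[RpRecord]
) -> GeneChainMap:
    """Map a gene symbol to the structure chain(s) carrying its protein.

    Applies the three-stage cascade described in the module docstring; the
    route of the first matching stage is recorded.  An unmatched gene returns
    an empty map whose route is the deepest stage attempted.
    """
    rec = find_record(gene, table)
    described = [
        (c.chain_id, _tokens(c.entity_description))
        for c in structure.chains
        if c.entity_description
    ]

    if rec is not None:
        # stage 1: universal name as a standalone token
        uni = _normalize(rec.universal_name)
        hits = [cid for cid, toks in described if uni in toks]
        if hits:
            return GeneChainMap(gene, sorted(set(hits)), "universal_name", "exact")
        # stage 2: legacy name as contiguous token run
        hits = [
            cid for cid, toks in described
            if any(_contains_token_run(toks, _tokens(name)) for name in rec.legacy_names)
        ]
        if hits:
            return GeneChainMap(gene, sorted(set(hits)), "legacy_name", "exact")

    # stage 3: L<number>/S<number> token from the gene symbol itself
    m = _GENE_NUMBER_RE.match(gene.strip())
    if m:
        token = (m.group(1) + m.group(2)).casefold()
        hits = [
            cid for cid, toks in described
            if token in toks and "ribosomal" in toks and "protein" in toks
        ]
        if hits:
            return GeneChainMap(gene, sorted(set(hits)), "entity_description", "fuzzy")

    return GeneChainMap(gene, [], "entity_description", "exact")


def gene_label(
    gene: str, exposures: Sequence[ChainExposure], gene_map: GeneChainMap
) -> GeneLabel:
    """surface / internal / unmapped verdict for one gene.

    A gene is surface when ANY of its matched chains is surface-labelled
    (a transcript's protein is surface-capable if any modelled copy is
    exposed).  Chains in the map must be present in the exposure set.
    """
    if not gene_map.matched_chain_ids:
        return "unmapped"
    by_chain = {e.chain_id: e.label for e in exposures}
    labels = []
    for cid in gene_map.matched_chain_ids:
        if cid not in by_chain:
            raise ConsistencyError(
                f"gene {gene}: mapped chain {cid} has no exposure record "
                "(classification ran on a different structure?)"
            )
        labels.append(by_chain[cid])
    return "surface" if "surface" in labels else "internal"
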