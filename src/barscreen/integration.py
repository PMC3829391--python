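"""Gene-list harmonization, offline disease-keyword querying and 3-set overlap.

Candidate nomination rests on agreement between independent lines of
evidence: a functional screen hit list, a phosphoproteomic hit list and a
disease-association list extracted from gene-record text.  Symbols are the
join key, so everything is harmonized (trimmed, uppercased, alias-resolved)
before any set arithmetic.

The disease list is built offline from a serialized gene-record dump
(JSON lines) rather than a live database query: keyword hits against a
public database are a function of its snapshot date and are not
reproducible otherwise.  A live-retrieval helper exists for users who want
a fresh dump, but no analysis or test depends on it.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceSet:
    """A named, harmonized set of gene symbols with free-text provenance."""

    name: str
    symbols: frozenset[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: int
    gene_symbol: str
    aliases: tuple[str, ...] = ()
    description: str = ""
    summary: str = ""


@dataclass
class GeneRecordDump:
    """An offline snapshot of gene records, one JSON object per line on disk."""

    records: list[GeneRecord] = field(default_factory=list)
    source_label: str = ""
    snapshot_date: str = ""

    def __post_init__(self):
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("gene_id values in a dump must be unique")


@dataclass(frozen=True)
class VennCounts:
    """Region structure of a 3-set overlap.

    Stores both the seven exclusive regions and the three pairwise totals;
    published overlap figures are sometimes one and sometimes the other, and
    carrying both makes either reading checkable
    (``ab_total = ab_only + abc`` and likewise for the other pairs).
    """

    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int
    ab_total: int
    ac_total: int
    bc_total: int
    union_size: int
    labels: tuple[str, str, str] = ("A", "B", "C")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only",
            "abc", "ab_total", "ac_total", "bc_total", "union_size")}
        d["labels"] = list(self.labels)
        return d


@dataclass(frozen=True)
class CandidateRecord:
    gene_symbol: str
    in_screen: bool
    in_phospho: bool
    in_disease: bool
    rank_key: int  # number of evidence sets containing the gene


def harmonize(
    raw_symbols: Iterable[str],
    alias_map: Mapping[str, str] | None = None,
    name: str = "",
    provenance: str = "",
) -> EvidenceSet:
    """Trim, uppercase, alias-resolve and deduplicate a raw symbol list.

    Alias resolution happens after case/whitespace normalization, so the map
    matches regardless of input casing.  Entries absent from the map are kept
    verbatim-uppercased and logged (they may be novel or simply unaliased).
    """
    resolved: dict[str, str] = {}
    if alias_map:
        resolved = {k.strip().upper(): v.strip().upper() for k, v in alias_map.items()}
    out = set()
    unresolved = []
    for raw in raw_symbols:
        sym = str(raw).strip().upper()
        if not sym:
            continue
        if sym in resolved:
            out.add(resolved[sym])
        else:
            if alias_map:
                unresolved.append(sym)
            out.add(sym)
    if unresolved:
        log.info(
            "harmonize(%s): %d symbol(s) not in alias map, kept verbatim",
            name, len(unresolved),
        )
    return EvidenceSet(name=name, symbols=frozenset(out), provenance=provenance)


def read_symbol_list(path) -> list[str]:
    """One symbol per line (or first column of a TSV); '#' lines skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0])
    return out


def write_gene_dump(dump: GeneRecordDump, path) -> None:
    with open(path, "w") as fh:
        if dump.source_label or dump.snapshot_date:
            fh.write(json.dumps({
                "_meta": {"source_label": dump.source_label,
                          "snapshot_date": dump.snapshot_date}}) + "\n")
        for r in dump.records:
            fh.write(json.dumps({
                "gene_id": r.gene_id,
                "gene_symbol": r.gene_symbol,
                "aliases": list(r.aliases),
                "description": r.description,
                "summary": r.summary,
            }) + "\n")


def read_gene_dump(path) -> GeneRecordDump:
    records = []
    source_label = snapshot_date = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "_meta" in obj:
                source_label = obj["_meta"].get("source_label", "")
                snapshot_date = obj["_meta"].get("snapshot_date", "")
                continue
            records.append(GeneRecord(
                gene_id=int(obj["gene_id"]),
                gene_symbol=str(obj["gene_symbol"]),
                aliases=tuple(obj.get("aliases", ())),
                description=obj.get("description", ""),
                summary=obj.get("summary", ""),
            ))
    return GeneRecordDump(records, source_label, snapshot_date)


def query_disease_genes(
    dump: GeneRecordDump, keyword: str, whole_word: bool = True
) -> EvidenceSet:
    """Genes whose description or summary mentions ``keyword``.

    Matching is case-insensitive; with ``whole_word`` (default) the keyword
    must not be embedded in a longer word, so e.g. a query for a disease
    name does not match derived compound words.  Provenance records which
    field matched for each gene.
    """
    if not dump.records:
        raise ValueError("gene-record dump is empty")
    if not keyword or not keyword.strip():
        raise ValueError("keyword must be non-empty")
    kw = re.escape(keyword.strip())
    pattern = re.compile(
        rf"(?<!\w){kw}(?!\w)" if whole_word else kw, flags=re.IGNORECASE
    )
    matched = {}
    for rec in dump.records:
        fields = []
        if pattern.search(rec.description):
            fields.append("description")
        if pattern.search(rec.summary):
            fields.append("summary")
        if fields:
            matched[rec.gene_symbol.strip().upper()] = "+".join(fields)
    provenance = (
        f"keyword={keyword!r} whole_word={whole_word} "
        f"source={dump.source_label!r} snapshot={dump.snapshot_date!r}; "
        + "; ".join(f"{s}:{f}" for s, f in sorted(matched.items()))
    )
    return EvidenceSet(
        name=f"{keyword}-associated", symbols=frozenset(matched), provenance=provenance
    )


def venn3(a: EvidenceSet, b: EvidenceSet, c: EvidenceSet) -> VennCounts:
    """Exact 3-set region counts and pairwise totals."""
    A, B, C = a.symbols, b.symbols, c.symbols
    abc = A & B & C
    return VennCounts(
        a_only=len(A - B - C),
        b_only=len(B - A - C),
        c_only=len(C - A - B),
        ab_only=len((A & B) - C),
        ac_only=len((A & C) - B),
        bc_only=len((B & C) - A),
        abc=len(abc),
        ab_total=len(A & B),
        ac_total=len(A & C),
        bc_total=len(B & C),
        union_size=len(A | B | C),
        labels=(a.name or "A", b.name or "B", c.name or "C"),
    )


def nominate(
    screen: EvidenceSet, phospho: EvidenceSet, disease: EvidenceSet
) -> list[CandidateRecord]:
    """Rank genes supported by at least two evidence sets.

    Triple-overlap genes come first (rank 3), then double-overlap genes,
    alphabetically within rank.  Purely deterministic in the three sets.
    """
    out = []
    for sym in screen.symbols | phospho.symbols | disease.symbols:
        flags = (sym in screen.symbols, sym in phospho.symbols, sym in disease.symbols)
        rank = sum(flags)
        if rank >= 2:
            out.append(CandidateRecord(sym, *flags, rank_key=rank))
    out.sort(key=lambda r: (-r.rank_key, r.gene_symbol))
    return out


def candidates_frame(candidates: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_symbol": c.gene_symbol,
                "in_screen": c.in_screen,
                "in_phospho": c.in_phospho,
                "in_disease": c.in_disease,
                "rank_key": c.rank_key,
            }
            for c in candidates
        ],
        columns=["gene_symbol", "in_screen", "in_phospho", "in_disease", "rank_key"],
    )


def fetch_gene_records(symbols, email, source_label="ncbi-gene-live"):
    """Live retrieval of gene records via NCBI Entrez (requires biopython
    and network access).  Convenience for building a fresh dump only; the
    analysis itself always consumes a serialized snapshot."""
    from Bio import Entrez  # deliberate local import: optional dependency

    Entrez.email = email
    records = []
    for i, sym in enumerate(symbols):
        handle = Entrez.esearch(db="gene", term=f"{sym}[sym] AND human[orgn]")
        result = Entrez.read(handle)
        if not result["IdList"]:
            continue
        gid = int(result["IdList"][0])
        sh = Entrez.esummary(db="gene", id=str(gid))
        summ = Entrez.read(sh)["DocumentSummarySet"]["DocumentSummary"][0]
        records.append(GeneRecord(
            gene_id=gid,
            gene_symbol=sym,
            aliases=tuple(str(summ.get("OtherAliases", "")).split(", ")),
            description=str(summ.get("Description", "")),
            summary=str(summ.get("Summary", "")),
        ))
    from datetime import date

    return GeneRecordDump(records, source_label, date.today().isoformat())
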