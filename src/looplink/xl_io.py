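"""Reading sequences and cross-link identification tables.

Cross-linking mass spectrometry (XL-MS) search engines emit one result
table per technical replicate, listing pairs of cross-linked residue
positions together with decoy annotations and peptide coordinates.  This
module parses those tables (column names are user-configurable, since
dialects differ between search-engine versions), filters decoy and
homeotypic entries, and collapses the surviving records into a canonical
:class:`CrossLinkSet` — a multiset of unordered residue-site pairs.
Duplicate observations of the same site pair are deliberately retained as
multiplicities: how often a pair is re-observed carries chemical
information about the accessibility of its reaction sites.

Site enumeration targets the residues the DSBU linker reacts with:
lysine, serine, threonine and tyrosine (plus, optionally, the protein
N-terminus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .exceptions import FormatError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: Residues reactive toward the DSBU cross-linker.
LINKABLE_RESIDUES = frozenset("KSTY")

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based residue indexing."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SiteSet:
    """Cross-linkable residue positions of one protein (1-based, sorted)."""

    protein_id: str
    sites: tuple[int, ...]
    include_nterm: bool = False

    @property
    def n(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class CrossLinkRecord:
    """One identified cross-link, as reported by the search engine."""

    protein_a: str
    protein_b: str
    site_a: int
    site_b: int
    replicate_id: str
    score: float = 0.0
    is_decoy: bool = False
    peptide_a_span: tuple[int, int] | None = None
    peptide_b_span: tuple[int, int] | None = None


@dataclass
class FilterCounts:
    """Bookkeeping of records excluded while building a CrossLinkSet."""

    n_input: int = 0
    n_decoy: int = 0
    n_inter_protein: int = 0
    n_homeotypic: int = 0
    n_self_pair: int = 0
    n_below_score: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


@dataclass(frozen=True)
class CrossLinkSet:
    """Canonical multiset of unordered intra-molecular site pairs.

    ``pairs`` maps each canonical pair ``(min(i, j), max(i, j))`` to its
    multiplicity (number of observations across replicates);
    ``provenance`` maps the same pair to the replicate ids of those
    observations, in input order.
    """

    protein_id: str
    pairs: Mapping[tuple[int, int], int]
    provenance: Mapping[tuple[int, int], tuple[str, ...]]
    filter_counts: FilterCounts | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for (i, j), mult in self.pairs.items():
            if i >= j:
                raise ValueError(f"pair {(i, j)} is not canonical (need i < j)")
            if mult != len(self.provenance[(i, j)]):
                raise ValueError(f"pair {(i, j)}: multiplicity != provenance length")

    @property
    def unique_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.pairs))

    @property
    def total_observations(self) -> int:
        return sum(self.pairs.values())

    def observations(self) -> list[tuple[int, int]]:
        """The observation multiset: each pair repeated by multiplicity, sorted."""
        out: list[tuple[int, int]] = []
        for pair in sorted(self.pairs):
            out.extend([pair] * self.pairs[pair])
        return out


@dataclass(frozen=True)
class TableSchema:
    """Column-name mapping for a cross-link result table.

    ``site_a``/``site_b`` are required.  Sites may carry a residue-letter
    prefix (e.g. ``K190``) which is stripped when ``strip_site_prefix``
    is set.  ``decoy_marker`` is the cell value flagging a decoy row in
    the ``decoy`` column.
    """

    site_a: str = "site_a"
    site_b: str = "site_b"
    protein_a: str | None = "protein_a"
    protein_b: str | None = "protein_b"
    decoy: str | None = "is_decoy"
    decoy_marker: str = "decoy"
    score: str | None = "score"
    replicate: str | None = "replicate"
    peptide_a_from: str | None = None
    peptide_a_to: str | None = None
    peptide_b_from: str | None = None
    peptide_b_to: str | None = None
    strip_site_prefix: bool = True
    delimiter: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**raw)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records, in file order."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    first_content = next(
        ((n, ln) for n, ln in enumerate(lines, 1) if ln.strip()), None
    )
    if first_content is None:
        raise FormatError(f"{path}: empty FASTA file")
    if not first_content[1].startswith(">"):
        raise FormatError(
            f"{path}: line {first_content[0]} is not a FASTA header ('>' expected)"
        )
    records = [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def enumerate_sites(seq: ProteinSequence, include_nterm: bool = False) -> SiteSet:
    """All 1-based K/S/T/Y positions; optionally prepend the N-terminus."""
    sites = [i for i, aa in enumerate(seq.residues, 1) if aa in LINKABLE_RESIDUES]
    if include_nterm and (not sites or sites[0] != 1):
        sites.insert(0, 1)
    return SiteSet(protein_id=seq.id, sites=tuple(sites), include_nterm=include_nterm)


def count_possible_pairs(sites: SiteSet) -> int:
    """Theoretical maximum of distinct cross-links: n(n-1)/2 unordered pairs."""
    n = sites.n
    return n * (n - 1) // 2


def _parse_site(value: object, row: int, column: str, strip_prefix: bool) -> int:
    text = str(value).strip()
    if strip_prefix:
        text = text.lstrip("ACDEFGHIKLMNPQRSTVWYX")
    try:
        return int(text)
    except ValueError:
        raise ParseError(
            f"row {row}: column {column!r} value {value!r} is not a residue index"
        ) from None


def read_xl_table(
    path: str | Path,
    schema: TableSchema = TableSchema(),
    replicate_id: str | None = None,
) -> list[CrossLinkRecord]:
    """Parse one delimited cross-link result table into records.

    ``replicate_id`` overrides the schema's replicate column (useful when
    the replicate identity is encoded in the file name, as is common for
    per-run result exports).
    """
    path = Path(path)
    sep = schema.delimiter
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    required = {"site_a": schema.site_a, "site_b": schema.site_b}
    for logical, column in required.items():
        if column not in df.columns:
            raise SchemaError(
                f"{path}: mapped column {column!r} (for {logical}) not in header "
                f"{list(df.columns)}"
            )
    optional = {
        name: getattr(schema, name)
        for name in ("protein_a", "protein_b", "decoy", "score", "replicate",
                     "peptide_a_from", "peptide_a_to", "peptide_b_from", "peptide_b_to")
        if getattr(schema, name) is not None
    }
    for logical, column in optional.items():
        if column not in df.columns:
            raise SchemaError(
                f"{path}: mapped column {column!r} (for {logical}) not in header"
            )

    records: list[CrossLinkRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), 2):  # 2 = first data line
        get = dict(zip(df.columns, row)).get
        site_a = _parse_site(get(schema.site_a), idx, schema.site_a, schema.strip_site_prefix)
        site_b = _parse_site(get(schema.site_b), idx, schema.site_b, schema.strip_site_prefix)
        protein_a = str(get(schema.protein_a, "")) if schema.protein_a else ""
        protein_b = str(get(schema.protein_b, "")) if schema.protein_b else ""
        is_decoy = False
        if schema.decoy:
            is_decoy = str(get(schema.decoy, "")).strip().lower() == schema.decoy_marker.lower()
        score = 0.0
        if schema.score:
            raw = str(get(schema.score, "")).strip()
            score = float(raw) if raw else 0.0
        rep = replicate_id
        if rep is None:
            rep = str(get(schema.replicate, "")) if schema.replicate else path.stem
        span_a = span_b = None
        if schema.peptide_a_from and schema.peptide_a_to:
            span_a = (_parse_site(get(schema.peptide_a_from), idx, schema.peptide_a_from, False),
                      _parse_site(get(schema.peptide_a_to), idx, schema.peptide_a_to, False))
        if schema.peptide_b_from and schema.peptide_b_to:
            span_b = (_parse_site(get(schema.peptide_b_from), idx, schema.peptide_b_from, False),
                      _parse_site(get(schema.peptide_b_to), idx, schema.peptide_b_to, False))
        records.append(
            CrossLinkRecord(
                protein_a=protein_a, protein_b=protein_b,
                site_a=site_a, site_b=site_b,
                replicate_id=rep, score=score, is_decoy=is_decoy,
                peptide_a_span=span_a, peptide_b_span=span_b,
            )
        )
    return records


def is_homeotypic(record: CrossLinkRecord) -> bool:
    """Whether a record links two copies of the same peptide.

    When both peptide spans are present, the record is homeotypic if the
    spans overlap as residue intervals (a peptide cross-linked to a copy
    of itself is evidence of an inter-molecular dimer contact, not of
    intra-molecular structure).  Without spans, fall back to identical
    sites.
    """
    a, b = record.peptide_a_span, record.peptide_b_span
    if a is not None and b is not None:
        return a[0] <= b[1] and b[0] <= a[1]
    return record.site_a == record.site_b


def to_crosslink_set(
    records: Sequence[CrossLinkRecord],
    protein_id: str,
    min_score: float | None = None,
) -> CrossLinkSet:
    """Filter records and collapse them into a canonical CrossLinkSet.

    Drops decoys, inter-protein records, homeotypic records and self-pairs
    (site_a == site_b); all exclusions are counted and logged.  Records
    are assumed pre-filtered by the search engine's statistical criteria;
    ``min_score`` adds an optional extra threshold (off by default).
    """
    counts = FilterCounts(n_input=len(records))
    pairs: dict[tuple[int, int], int] = {}
    provenance: dict[tuple[int, int], list[str]] = {}
    for rec in records:
        if rec.is_decoy:
            counts.n_decoy += 1
            continue
        if rec.protein_a and rec.protein_b and rec.protein_a != rec.protein_b:
            counts.n_inter_protein += 1
            continue
        if is_homeotypic(rec):
            counts.n_homeotypic += 1
            continue
        if rec.site_a == rec.site_b:
            counts.n_self_pair += 1
            continue
        if min_score is not None and rec.score < min_score:
            counts.n_below_score += 1
            continue
        pair = (min(rec.site_a, rec.site_b), max(rec.site_a, rec.site_b))
        pairs[pair] = pairs.get(pair, 0) + 1
        provenance.setdefault(pair, []).append(rec.replicate_id)
        counts.n_kept += 1
    logger.info(
        "to_crosslink_set[%s]: kept %d/%d (decoy=%d inter=%d homeotypic=%d "
        "self=%d below_score=%d)",
        protein_id, counts.n_kept, counts.n_input, counts.n_decoy,
        counts.n_inter_protein, counts.n_homeotypic, counts.n_self_pair,
        counts.n_below_score,
    )
    return CrossLinkSet(
        protein_id=protein_id,
        pairs={p: pairs[p] for p in sorted(pairs)},
        provenance={p: tuple(provenance[p]) for p in sorted(provenance)},
        filter_counts=counts,
    )


def write_crosslink_tsv(xls: CrossLinkSet, path: str | Path) -> None:
    """Export a CrossLinkSet in the canonical internal TSV layout."""
    rows = [
        {
            "protein": xls.protein_id,
            "site_a": i,
            "site_b": j,
            "multiplicity": xls.pairs[(i, j)],
            "replicates": ";".join(xls.provenance[(i, j)]),
        }
        for (i, j) in sorted(xls.pairs)
    ]
    pd.DataFrame(rows, columns=["protein", "site_a", "site_b", "multiplicity",
                                "replicates"]).to_csv(path, sep="\t", index=False)


def read_crosslink_tsv(path: str | Path) -> CrossLinkSet:
    """Read back the canonical TSV written by :func:`write_crosslink_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"site_a": int, "site_b": int,
                                            "multiplicity": int})
    if df.empty:
        raise FormatError(f"{path}: empty cross-link TSV")
    protein_id = str(df["protein"].iloc[0])
    pairs: dict[tuple[int, int], int] = {}
    provenance: dict[tuple[int, int], tuple[str, ...]] = {}
    for row in df.itertuples(index=False):
        pair = (int(row.site_a), int(row.site_b))
        pairs[pair] = int(row.multiplicity)
        provenance[pair] = tuple(str(row.replicates).split(";"))
    return CrossLinkSet(protein_id=protein_id, pairs=pairs, provenance=provenance)


def merge_crosslink_sets(sets: Iterable[CrossLinkSet]) -> CrossLinkSet:
    """Pool several replicate CrossLinkSets of the same protein."""
    sets = list(sets)
    if not sets:
        raise ValueError("no sets to merge")
    protein_id = sets[0].protein_id
    pairs: dict[tuple[int, int], int] = {}
    provenance: dict[tuple[int, int], list[str]] = {}
    for s in sets:
        if s.protein_id != protein_id:
            raise ValueError("cannot merge sets from different proteins")
        for pair, mult in s.pairs.items():
            pairs[pair] = pairs.get(pair, 0) + mult
            provenance.setdefault(pair, []).extend(s.provenance[pair])
    return CrossLinkSet(
        protein_id=protein_id,
        pairs={p: pairs[p] for p in sorted(pairs)},
        provenance={p: tuple(provenance[p]) for p in sorted(provenance)},
    )
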