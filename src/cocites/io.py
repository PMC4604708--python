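"""Citation-corpus I/O and cited-reference canonicalisation.

Citation databases export, for every citing article, the whole reference
list as formatted strings.  Counting how often a work is co-cited requires
collapsing the many string variants of the same cited work onto one
canonical identity.  This module provides

* :class:`CitedReference` — a best-effort parse of one reference string,
* :func:`make_refkey` — the deterministic identity rule (DOI when present,
  otherwise a normalised author/year/source/volume/page composite),
* :class:`ArticleRecord` / :class:`CitationCorpus` — the in-memory corpus
  with its inverse citation map,
* readers for field-tagged (Web of Science style) exports, generic
  metadata + edge-list CSV pairs and the internal JSON corpus format, and
  a writer for ranked candidate tables.

Readers are total on their declared dialects: malformed optional fields
degrade to empty/unknown instead of raising.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .engine import CoCitationTable

logger = logging.getLogger("cocites")

#: Canonical identity of a cited work (the unit being counted).
RefKey = str

#: Sentinel key for references with no usable bibliographic content.
UNUSABLE_KEY: RefKey = "unusable"

DOC_TYPES = ("article", "abstract", "review", "other", "unknown")

_YEAR_RE = re.compile(r"^(1[89]|20)\d{2}$")
_DOI_RE = re.compile(r"10\.\d{4,9}/\S+", re.IGNORECASE)
_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def is_usable_key(key: RefKey) -> bool:
    """True unless ``key`` is the sentinel produced from an all-empty reference."""
    return key != UNUSABLE_KEY


# ---------------------------------------------------------------------------
# Cited references and keys
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CitedReference:
    """One cited-reference string, parsed best effort.

    ``raw_string`` is preserved verbatim; parsing never mutates it.  ``year``
    is ``None`` when absent or outside [1800, 2100].
    """

    raw_string: str
    first_author_surname: str = ""
    year: Optional[int] = None
    source: str = ""
    volume: str = ""
    first_page: str = ""
    doi: str = ""


def _norm_component(text: str) -> str:
    """Lowercase, strip punctuation, collapse internal whitespace."""
    text = _PUNCT_RE.sub(" ", text.lower())
    return _WS_RE.sub(" ", text).strip()


def _norm_doi(doi: str) -> str:
    doi = doi.strip().lower()
    for prefix in ("https://doi.org/", "http://doi.org/", "http://dx.doi.org/", "doi:", "doi "):
        if doi.startswith(prefix):
            doi = doi[len(prefix):]
    return doi.strip().rstrip(".,;")


def _coerce_year(token: str) -> Optional[int]:
    token = token.strip()
    if _YEAR_RE.match(token):
        year = int(token)
        if 1800 <= year <= 2100:
            return year
    return None


def parse_cited_reference(raw: str, dialect: str = "wos") -> CitedReference:
    """Parse one cited-reference token.

    The ``wos`` dialect expects comma-separated fields in the conventional
    order ``AUTHOR, YEAR, SOURCE, Vvol, Ppage, DOI doi`` with any suffix
    fields optional.  The ``plain`` dialect applies the same field
    heuristics without assuming a fixed order for volume/page markers.
    Unparseable components are left empty; the function never raises on
    malformed content, only on blank input.
    """
    if dialect not in ("wos", "plain"):
        raise ValueError(f"unknown reference dialect: {dialect!r}")
    if not raw or not raw.strip():
        raise ValueError("blank cited-reference token")
    text = raw.strip()

    doi = ""
    m = _DOI_RE.search(text)
    if m:
        doi = _norm_doi(m.group(0))

    tokens = [t.strip() for t in text.split(",")]
    surname = ""
    year: Optional[int] = None
    source = ""
    volume = ""
    first_page = ""

    rest: list[str] = []
    for i, tok in enumerate(tokens):
        if i == 0:
            surname = tok
            continue
        if year is None and _coerce_year(tok) is not None:
            year = _coerce_year(tok)
            continue
        rest.append(tok)

    for tok in rest:
        upper = tok.upper()
        if upper.startswith("DOI"):
            continue  # captured by regex above
        if not volume and re.match(r"^V\S+$", upper):
            volume = tok[1:]
        elif not first_page and re.match(r"^P\S+$", upper):
            first_page = tok[1:]
        elif not source:
            source = tok

    return CitedReference(
        raw_string=raw,
        first_author_surname=surname,
        year=year,
        source=source,
        volume=volume,
        first_page=first_page,
        doi=doi,
    )


def make_refkey(ref: CitedReference) -> RefKey:
    """Canonical identity of a cited work.

    A non-empty DOI overrides everything else; otherwise the key is the
    normalised join ``surname|year|source|volume|page``.  Normalisation is
    lowercasing, punctuation stripping and whitespace collapsing, so keys
    are case- and whitespace-insensitive.  An all-empty reference yields
    the sentinel :data:`UNUSABLE_KEY`.
    """
    if ref.doi:
        return "doi:" + _norm_doi(ref.doi)
    parts = [
        _norm_component(ref.first_author_surname),
        str(ref.year) if ref.year is not None else "",
        _norm_component(ref.source),
        _norm_component(ref.volume),
        _norm_component(ref.first_page),
    ]
    if not any(parts):
        return UNUSABLE_KEY
    return "|".join(parts)


def refkey_from_string(raw: str, dialect: str = "wos") -> RefKey:
    """Convenience: parse then key in one step."""
    return make_refkey(parse_cited_reference(raw, dialect=dialect))


# ---------------------------------------------------------------------------
# Articles and corpora
# ---------------------------------------------------------------------------


@dataclass
class ArticleRecord:
    """One indexed article: metadata plus its outgoing reference list.

    ``cited_refs`` holds the canonical keys of the works on the article's
    reference list, in list order.  ``refkey`` is the article's own identity
    as a citable work; when empty it is derived from the metadata.
    ``references`` optionally keeps the parsed reference strings for
    faithful export round-trips; it does not participate in equality.
    """

    article_id: str
    title: str = ""
    first_author_surname: str = ""
    year: Optional[int] = None
    source: str = ""
    doi: str = ""
    language: str = ""
    doc_type: str = "unknown"
    cited_refs: list[RefKey] = field(default_factory=list)
    refkey: RefKey = ""
    references: Optional[list[CitedReference]] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.doc_type not in DOC_TYPES:
            self.doc_type = "other"
        if not self.refkey:
            self.refkey = make_refkey(
                CitedReference(
                    raw_string="",
                    first_author_surname=self.first_author_surname,
                    year=self.year,
                    source=self.source,
                    doi=self.doi,
                )
            )


class CitationCorpus:
    """A set of articles with the inverse map from cited work to citers.

    ``cited_by[k]`` is exactly the set of article ids whose reference list
    contains key ``k``.  Article identities (``refkey_of_article``) are
    injective: two indexed articles never share a key.
    """

    def __init__(self, articles: Iterable[ArticleRecord] = ()):
        self.articles: dict[str, ArticleRecord] = {}
        self.refkey_of_article: dict[str, RefKey] = {}
        self.article_of_refkey: dict[RefKey, str] = {}
        self.cited_by: dict[RefKey, set[str]] = {}
        for record in articles:
            self.add(record)

    def add(self, record: ArticleRecord) -> None:
        if record.article_id in self.articles:
            raise ValueError(f"duplicate article_id: {record.article_id!r}")
        key = record.refkey
        if is_usable_key(key):
            if key in self.article_of_refkey:
                raise ValueError(
                    f"article identity collision: {record.article_id!r} and "
                    f"{self.article_of_refkey[key]!r} share key {key!r}"
                )
            self.article_of_refkey[key] = record.article_id
        self.articles[record.article_id] = record
        self.refkey_of_article[record.article_id] = key
        for cited in record.cited_refs:
            self.cited_by.setdefault(cited, set()).add(record.article_id)

    def __len__(self) -> int:
        return len(self.articles)

    def __contains__(self, article_id: str) -> bool:
        return article_id in self.articles

    def __iter__(self) -> Iterator[ArticleRecord]:
        return iter(self.articles.values())

    def citers_of(self, key: RefKey) -> set[str]:
        return set(self.cited_by.get(key, set()))

    def validate(self) -> None:
        """Check the inverse-map invariant by brute force (test helper)."""
        rebuilt: dict[RefKey, set[str]] = {}
        for record in self:
            for key in record.cited_refs:
                rebuilt.setdefault(key, set()).add(record.article_id)
        if rebuilt != self.cited_by:
            raise AssertionError("cited_by map out of sync with reference lists")

    # -- JSON corpus format -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "cocites-corpus",
            "version": 1,
            "articles": [
                {
                    "article_id": a.article_id,
                    "title": a.title,
                    "first_author_surname": a.first_author_surname,
                    "year": a.year,
                    "source": a.source,
                    "doi": a.doi,
                    "language": a.language,
                    "doc_type": a.doc_type,
                    "refkey": a.refkey,
                    "cited_refs": list(a.cited_refs),
                }
                for a in sorted(self, key=lambda a: a.article_id)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CitationCorpus":
        payload = json.loads(Path(path).read_text(encoding="utf-8", errors="replace"))
        if not isinstance(payload, dict) or "articles" not in payload:
            raise ValueError(f"{path}: not a corpus JSON file (missing 'articles')")
        records = []
        for entry in payload["articles"]:
            records.append(
                ArticleRecord(
                    article_id=str(entry["article_id"]),
                    title=entry.get("title", ""),
                    first_author_surname=entry.get("first_author_surname", ""),
                    year=entry.get("year"),
                    source=entry.get("source", ""),
                    doi=entry.get("doi", ""),
                    language=entry.get("language", ""),
                    doc_type=entry.get("doc_type", "unknown"),
                    cited_refs=[str(k) for k in entry.get("cited_refs", [])],
                    refkey=entry.get("refkey", ""),
                )
            )
        return cls(records)


# ---------------------------------------------------------------------------
# Field-tagged exports
# ---------------------------------------------------------------------------

_TAGS = ("UT", "TI", "AU", "PY", "SO", "DI", "LA", "DT", "CR")


def _doc_type_from_dt(dt: str) -> str:
    low = dt.lower()
    if not low:
        return "unknown"
    if "abstract" in low:
        return "abstract"
    if "review" in low:
        return "review"
    if "article" in low:
        return "article"
    return "other"


def _surname_from_au(au: str) -> str:
    return au.split(",")[0].strip() if au else ""


def _record_from_fields(fields: Mapping[str, str], dialect: str) -> Optional[ArticleRecord]:
    article_id = fields.get("UT", "").strip()
    if not article_id:
        logger.warning("skipping export record with no UT identifier (title=%r)", fields.get("TI", ""))
        return None
    refs: list[CitedReference] = []
    cr = fields.get("CR", "").strip()
    if cr:
        for token in cr.split("; "):
            token = token.strip().rstrip(";")
            if token:
                refs.append(parse_cited_reference(token, dialect=dialect))
    return ArticleRecord(
        article_id=article_id,
        title=fields.get("TI", "").strip(),
        first_author_surname=_surname_from_au(fields.get("AU", "").strip()),
        year=_coerce_year(fields.get("PY", "")),
        source=fields.get("SO", "").strip(),
        doi=_norm_doi(fields.get("DI", "")) if fields.get("DI", "").strip() else "",
        language=fields.get("LA", "").strip(),
        doc_type=_doc_type_from_dt(fields.get("DT", "")),
        cited_refs=[make_refkey(r) for r in refs],
        references=refs,
    )


def _read_tagged_lines(lines: Sequence[str], dialect: str) -> list[ArticleRecord]:
    records: list[ArticleRecord] = []
    fields: dict[str, str] = {}
    current_tag = ""
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        tag, _, value = line.partition(" ") if not line.startswith("   ") else ("", "", line.strip())
        if line.startswith("   "):
            # continuation line: CR entries arrive one per line
            if current_tag:
                sep = "; " if current_tag == "CR" else " "
                fields[current_tag] = fields.get(current_tag, "") + sep + line.strip()
            continue
        tag = tag.strip()
        if tag == "ER":
            record = _record_from_fields(fields, dialect)
            if record is not None:
                records.append(record)
            fields = {}
            current_tag = ""
        elif tag in ("FN", "VR", "EF"):
            current_tag = ""
        else:
            current_tag = tag
            fields[tag] = value.strip()
    return records


def _read_tab_delimited(lines: Sequence[str], dialect: str) -> list[ArticleRecord]:
    header = lines[0].rstrip("\n").split("\t")
    records: list[ArticleRecord] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        values = line.rstrip("\n").split("\t")
        fields = {h: (values[i] if i < len(values) else "") for i, h in enumerate(header)}
        record = _record_from_fields(fields, dialect)
        if record is not None:
            records.append(record)
    return records


def read_wos_export(path: str | Path, dialect: str = "wos") -> list[ArticleRecord]:
    """Read a field-tagged bibliographic export.

    Both layouts of the tagged format are accepted: tab-delimited with a
    tag header row, and tag-per-line with three-space continuation lines
    and ``ER`` record terminators.  Cited references inside the ``CR``
    field are split on ``"; "`` and parsed with :func:`parse_cited_reference`.
    Records lacking a ``UT`` identifier are skipped with a warning.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty export file")
    if "\t" in lines[0]:
        records = _read_tab_delimited(lines, dialect)
    else:
        records = _read_tagged_lines(lines, dialect)
    if not records:
        raise ValueError(f"{path}: no records parsed; first line was {lines[0]!r}")
    return records


def write_wos_export(records: Sequence[ArticleRecord], path: str | Path) -> None:
    """Write records in the tab-delimited tagged layout (round-trips with the reader)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_TAGS) + "\n")
        for a in records:
            if a.references is not None:
                cr = "; ".join(r.raw_string for r in a.references)
            else:
                cr = "; ".join(a.cited_refs)
            row = {
                "UT": a.article_id,
                "TI": a.title,
                "AU": a.first_author_surname,
                "PY": str(a.year) if a.year is not None else "",
                "SO": a.source,
                "DI": a.doi,
                "LA": a.language,
                "DT": a.doc_type,
                "CR": cr,
            }
            fh.write("\t".join(row[t] for t in _TAGS) + "\n")


# ---------------------------------------------------------------------------
# Edge-list corpora
# ---------------------------------------------------------------------------


def read_edge_list(metadata_path: str | Path, edges_path: str | Path) -> CitationCorpus:
    """Build a corpus from a metadata CSV and a citing→cited edge CSV.

    The metadata file needs one row per article with at least an
    ``article_id`` column; the edge file needs ``citing_article_id`` and
    ``cited_refkey`` columns.  Edges whose citing id has no metadata row
    are an error (all offenders listed); duplicate article ids are an error.
    """
    records: dict[str, ArticleRecord] = {}
    with open(metadata_path, encoding="utf-8", errors="replace", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "article_id" not in reader.fieldnames:
            raise ValueError(f"{metadata_path}: metadata CSV needs an 'article_id' column")
        for row in reader:
            article_id = (row.get("article_id") or "").strip()
            if not article_id:
                continue
            if article_id in records:
                raise ValueError(f"{metadata_path}: duplicate article_id {article_id!r}")
            year_raw = (row.get("year") or "").strip()
            records[article_id] = ArticleRecord(
                article_id=article_id,
                title=(row.get("title") or "").strip(),
                first_author_surname=(row.get("first_author_surname") or "").strip(),
                year=_coerce_year(year_raw),
                source=(row.get("source") or "").strip(),
                doi=(row.get("doi") or "").strip(),
                language=(row.get("language") or "").strip(),
                doc_type=(row.get("doc_type") or "unknown").strip() or "unknown",
                refkey=(row.get("refkey") or "").strip(),
            )

    dangling: list[str] = []
    with open(edges_path, encoding="utf-8", errors="replace", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is not None and reader.fieldnames != [] and (
            "citing_article_id" not in reader.fieldnames or "cited_refkey" not in reader.fieldnames
        ):
            raise ValueError(
                f"{edges_path}: edge CSV needs 'citing_article_id' and 'cited_refkey' columns"
            )
        for row in reader:
            citing = (row.get("citing_article_id") or "").strip()
            cited = (row.get("cited_refkey") or "").strip()
            if not citing and not cited:
                continue
            if citing not in records:
                dangling.append(citing)
                continue
            records[citing].cited_refs.append(cited)
    if dangling:
        raise ValueError(
            f"{edges_path}: edges reference unknown citing ids: {sorted(set(dangling))}"
        )
    return CitationCorpus(records.values())


# ---------------------------------------------------------------------------
# Ranked output
# ---------------------------------------------------------------------------

RANKED_COLUMNS = ("rank", "refkey", "cocitation_count", "j_index", "is_known_seed", "display_reference")


def write_ranked_list(
    table: "CoCitationTable",
    path: str | Path,
    corpus: Optional[CitationCorpus] = None,
) -> None:
    """Write a ranked candidate table as CSV, descending by co-citation count.

    Output is byte-identical across re-runs of the same table.  When a
    corpus is supplied, indexed candidates get a human-readable
    ``display_reference`` built from their metadata; otherwise the key
    itself is displayed.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RANKED_COLUMNS)
        for rec in table.records:
            display = rec.refkey
            if corpus is not None:
                article_id = corpus.article_of_refkey.get(rec.refkey)
                if article_id is not None:
                    a = corpus.articles[article_id]
                    bits = [a.first_author_surname, str(a.year) if a.year else "", a.source]
                    display = ", ".join(b for b in bits if b) or rec.refkey
            writer.writerow(
                [
                    rec.rank,
                    rec.refkey,
                    rec.cocitation_count,
                    format(rec.j_index, ".10g"),
                    str(rec.refkey in table.seed_keys),
                    display,
                ]
            )


def read_ranked_list(path: str | Path) -> "CoCitationTable":
    """Read a ranked CSV back into a table.

    ``n_citing`` is not a CSV column; it is recovered from the top row via
    ``count / j_index`` (exact for any realistic table size, since the
    j-index is written with 10 significant digits).
    """
    from .engine import CoCitationRecord, CoCitationTable

    records: list[CoCitationRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(
                CoCitationRecord(
                    refkey=row["refkey"],
                    cocitation_count=int(row["cocitation_count"]),
                    j_index=float(row["j_index"]),
                    rank=int(row["rank"]),
                )
            )
    if records:
        n_citing = int(round(100.0 * records[0].cocitation_count / records[0].j_index))
    else:
        n_citing = 0
    return CoCitationTable(records=records, n_citing=n_citing, seed_keys=set(), provenance={})
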