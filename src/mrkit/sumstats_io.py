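"""Read, validate and write GWAS summary statistics as delimited text.

The de-facto interchange format for GWAS summary data is a delimited text
file with one SNP per row and a header naming, in some local dialect, the
identifier, effect/other allele, effect estimate (log odds ratio for binary
traits), its standard error, the effect-allele frequency, the association
p-value and the sample size.  ``read_sumstats`` maps any such dialect onto a
canonical record via a user-supplied column map, enforces per-record
invariants (dropping and counting offending rows), and returns an ordered,
uniquely-keyed :class:`SummaryStats` container.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ColumnMappingError, EmptyInputError

__all__ = [
    "SNPRecord",
    "SummaryStats",
    "ParseReport",
    "read_sumstats",
    "write_sumstats",
    "write_table",
    "CANONICAL_FIELDS",
]

CANONICAL_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se",
                    "eaf", "pval", "n")
#: every canonical field except ``eaf`` must be mapped and non-missing
MANDATORY_FIELDS = tuple(f for f in CANONICAL_FIELDS if f != "eaf")

VALID_BASES = frozenset("ACGT")
#: tokens treated as a missing value (case-insensitive)
MISSING_TOKENS = frozenset({"", "na", "nan", "null", "."})


def _is_missing(token: str) -> bool:
    return token.strip().lower() in MISSING_TOKENS


@dataclass(frozen=True, slots=True)
class SNPRecord:
    """One SNP association record for a single trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log odds scale for binary traits).  ``eaf`` may be ``None`` (unknown
    effect-allele frequency); every other field is mandatory.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None
    pval: float
    n: int

    def __post_init__(self):
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValueError(f"{self.snp_id}: alleles must be single bases A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.snp_id}: eaf must be in (0, 1) or missing")
        if self.n <= 0:
            raise ValueError(f"{self.snp_id}: n must be a positive integer")


@dataclass
class ParseReport:
    """Bookkeeping for one file parse: rows read, kept, and dropped by reason."""

    rows_read: int = 0
    rows_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class SummaryStats:
    """Ordered collection of :class:`SNPRecord` for one trait, keyed by snp_id."""

    trait_label: str
    records: dict[str, SNPRecord]
    provenance: str = ""
    parse_report: ParseReport | None = None

    def __post_init__(self):
        # dict keys enforce uniqueness; verify keys agree with record ids
        for key, rec in self.records.items():
            if key != rec.snp_id:
                raise ValueError(f"record keyed {key!r} has snp_id {rec.snp_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> SNPRecord:
        return self.records[snp_id]

    def __iter__(self):
        return iter(self.records.values())

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStats":
        """New SummaryStats restricted to ``snp_ids``, preserving their order."""
        recs = {s: self.records[s] for s in snp_ids}
        return SummaryStats(self.trait_label, recs, self.provenance)

    @classmethod
    def from_records(cls, trait_label: str, records: Sequence[SNPRecord],
                     provenance: str = "") -> "SummaryStats":
        recs: dict[str, SNPRecord] = {}
        for r in records:
            if r.snp_id in recs:
                raise ValueError(f"duplicate snp_id {r.snp_id!r}")
            recs[r.snp_id] = r
        return cls(trait_label, recs, provenance)


def _detect_delimiter(path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def _parse_row(values: Mapping[str, str]) -> tuple[SNPRecord | None, str | None]:
    """Validate one raw row; return (record, None) or (None, drop_reason)."""
    for f in MANDATORY_FIELDS:
        if _is_missing(values[f]):
            return None, "missing_value"
    ea = values["effect_allele"].strip().upper()
    oa = values["other_allele"].strip().upper()
    if ea not in VALID_BASES or oa not in VALID_BASES or ea == oa:
        return None, "non_snp"
    try:
        beta = float(values["beta"])
        se = float(values["se"])
        pval = float(values["pval"])
        n = int(float(values["n"]))
    except ValueError:
        return None, "unparseable"
    if not all(math.isfinite(x) for x in (beta, se, pval)):
        return None, "unparseable"
    if not se > 0:
        return None, "nonpositive_se"
    if not (0 < pval <= 1):
        return None, "bad_pval"
    if n <= 0:
        return None, "bad_n"
    eaf: float | None = None
    if not _is_missing(values["eaf"]):
        try:
            eaf = float(values["eaf"])
        except ValueError:
            return None, "unparseable"
        if not (0 < eaf < 1) or not math.isfinite(eaf):
            return None, "bad_eaf"
    return SNPRecord(values["snp_id"].strip(), ea, oa, beta, se, eaf, pval, n), None


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  trait_label: str = "", delimiter: str | None = None) -> SummaryStats:
    """Read one GWAS summary-statistic file into a :class:`SummaryStats`.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Mapping from canonical field names (``snp_id``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, ``eaf``, ``pval``, ``n``) to the
        column names used in the file.  Unmapped fields default to their
        canonical name.  All fields except ``eaf`` are mandatory.
    delimiter:
        Explicit delimiter; autodetected (tab, comma, whitespace) if ``None``.

    Rows violating record invariants are dropped and tallied by reason in the
    attached :class:`ParseReport`.
    """
    cmap = dict(column_map or {})
    resolved = {f: cmap.get(f, f) for f in CANONICAL_FIELDS}

    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     engine="python" if sep == r"\s+" else "c")

    eaf_col = resolved["eaf"]
    have_eaf = eaf_col in df.columns
    for f in MANDATORY_FIELDS:
        if resolved[f] not in df.columns:
            raise ColumnMappingError(
                f"mandatory column {resolved[f]!r} (field {f!r}) not found in {path}")

    report = ParseReport(rows_read=len(df))
    records: dict[str, SNPRecord] = {}
    cols = {f: df[resolved[f]].tolist() for f in MANDATORY_FIELDS}
    cols["eaf"] = df[eaf_col].tolist() if have_eaf else [""] * len(df)
    for i in range(len(df)):
        row = {f: cols[f][i] for f in CANONICAL_FIELDS}
        rec, reason = _parse_row(row)
        if rec is None:
            report.dropped[reason] += 1
            continue
        if rec.snp_id in records:
            report.dropped["duplicate_id"] += 1
            continue
        records[rec.snp_id] = rec
    report.rows_kept = len(records)

    if not records:
        raise EmptyInputError(f"no valid SNP rows in {path} "
                              f"(read {report.rows_read}, dropped {dict(report.dropped)})")
    return SummaryStats(trait_label or str(path), records, provenance=str(path),
                        parse_report=report)


def _format_value(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return repr(v)  # shortest exact round-trip representation
    return str(v)


def write_table(rows: Sequence[Mapping], path) -> None:
    """Write flat records as tab-delimited text with a header.

    All rows must share a field set; ``None``/NaN serialize as ``NA``.
    Floats use the shortest round-trip decimal representation, so a
    write/read cycle is lossless well beyond 12 significant digits.
    """
    rows = list(rows)
    if rows:
        fields = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != fields:
                raise ValueError("all records must share one field set")
    else:
        fields = []
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for r in rows:
            fh.write("\t".join(_format_value(r[f]) for f in fields) + "\n")


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write a SummaryStats as canonical tab-delimited text (round-trips
    through :func:`read_sumstats` with no column map)."""
    rows = [{"snp_id": r.snp_id, "effect_allele": r.effect_allele,
             "other_allele": r.other_allele, "beta": r.beta, "se": r.se,
             "eaf": r.eaf, "pval": r.pval, "n": r.n} for r in ss]
    if not rows:
        rows = []
        with open(path, "w") as fh:
            fh.write("\t".join(CANONICAL_FIELDS) + "\n")
        return
    write_table(rows, path)
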