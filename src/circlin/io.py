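"""Readers and writers for every table the pipeline touches.

All files are plain TSV, UTF-8, with a mandatory header row; ``.`` and
``NA`` denote missing values. Two external dialects are supported on
input: CIRI2 back-splice tables (one file per sample) and STAR
``SJ.out.tab`` splice-junction tables. Everything else uses the
package's own column schemas, which round-trip exactly.

Coordinates are 1-based inclusive throughout (the CIRI2 convention).
STAR reports intron bounds, which are converted to exonic junction
positions on read: donor = intron_start - 1, acceptor = intron_end + 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NA_VALUES = [".", "NA", ""]

#: column order of the generic linear-junction schema
LINEAR_COLUMNS = ["chrom", "donor_pos", "acceptor_pos", "strand", "sample_id", "count"]

#: column order of long-format qPCR Ct records
CT_COLUMNS = ["target_id", "isoform", "sample_id", "replicate", "ct"]

#: column order of splicing (gel band / PSI) records
SPLICING_COLUMNS = [
    "event_name",
    "direction",
    "sample_id",
    "incl_intensity",
    "excl_intensity",
    "percent",
]

VALID_STRANDS = {"+", "-", "."}
VALID_GROUPS = {"case", "control"}
VALID_ISOFORMS = {"circular", "linear", "reference"}
VALID_DIRECTIONS = {"exclusion", "inclusion"}

#: plausible qPCR cycle window; records outside are rejected on read
CT_WINDOW = (5.0, 40.0)


class FormatError(ValueError):
    """A table does not conform to its declared dialect."""


def event_id_for(chrom: str, start: int, end: int) -> str:
    """Canonical back-splice event identifier ``chrom:start|end``."""
    return f"{chrom}:{start}|{end}"


@dataclass(frozen=True)
class BackspliceEvent:
    """One circRNA locus keyed by its back-splice junction coordinates.

    ``start`` is the first base of the circRNA (acceptor side on the +
    strand), ``end`` the last base (donor side on the + strand); both
    1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for event {self.chrom}:{self.start}|{self.end}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def event_id(self) -> str:
        return event_id_for(self.chrom, self.start, self.end)

    def donor_acceptor(self) -> tuple[int, int]:
        """(donor, acceptor) junction coordinates under this strand.

        On the + strand the back-splice donor is the event end and the
        acceptor the event start; reversed on the - strand. For ``.``
        the + orientation is returned; callers that must match either
        orientation should treat the pair as unordered.
        """
        if self.strand == "-":
            return self.start, self.end
        return self.end, self.start


@dataclass
class JunctionCountTable:
    """Back-splice events x samples count matrix.

    Parameters
    ----------
    events
        DataFrame indexed by ``event_id`` with columns
        ``chrom, start, end, strand, gene_id``, one row per event.
    counts
        DataFrame indexed like ``events`` with one column per sample;
        raw junction-read integers, or reals after per-million
        normalization.
    normalized
        Whether ``counts`` are per-million normalized.
    lib_sizes
        Per-sample library sizes (reads); required while
        ``normalized`` is False.
    """

    events: pd.DataFrame
    counts: pd.DataFrame
    normalized: bool = False
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.events.index.equals(self.counts.index):
            raise ValueError("events and counts indices differ")
        if self.events.index.has_duplicates:
            raise ValueError("duplicate event_id in table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative junction counts")
        if not self.normalized:
            if self.lib_sizes is None:
                raise ValueError("raw counts require lib_sizes")
            missing = set(self.counts.columns) - set(self.lib_sizes.index)
            if missing:
                raise ValueError(f"lib_sizes missing for samples: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def event_ids(self) -> list[str]:
        return list(self.events.index)


# ---------------------------------------------------------------------------
# CIRI2 back-splice tables
# ---------------------------------------------------------------------------

_CIRI_REQUIRED = {
    "circRNA_ID": "circRNA_ID",
    "chr": "chrom",
    "circRNA_start": "start",
    "circRNA_end": "end",
    "junction_reads": "count",
    "strand": "strand",
    "gene_id": "gene_id",
}


def read_ciri_table(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read one sample's CIRI2 output into back-splice count records.

    Required columns: ``circRNA_ID, chr, circRNA_start, circRNA_end,
    #junction_reads`` (the leading ``#`` is optional), ``strand,
    gene_id``; extra columns are ignored. Coordinates are re-derived
    into the canonical ``chrom:start|end`` id and checked against the
    file's ``circRNA_ID``; on mismatch the coordinates win with a
    warning. Duplicate rows for one junction are summed with a warning
    (CIRI2 should not emit them; summing is lossless).

    Returns a DataFrame with columns
    ``event_id, chrom, start, end, strand, gene_id, sample_id, count``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_VALUES, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in _CIRI_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required CIRI2 column(s): {', '.join(missing)}")
    df = df[list(_CIRI_REQUIRED)].rename(columns=_CIRI_REQUIRED)
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["count"] = df["count"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric coordinate or count: {exc}") from None
    if (df["count"] < 0).any():
        raise FormatError(f"{path}: negative junction_reads")
    bad_strand = ~df["strand"].isin(VALID_STRANDS)
    if bad_strand.any():
        raise FormatError(f"{path}: invalid strand value {df.loc[bad_strand, 'strand'].iloc[0]!r}")
    df["gene_id"] = df["gene_id"].fillna("")

    derived = [event_id_for(c, s, e) for c, s, e in zip(df["chrom"], df["start"], df["end"])]
    mismatch = df["circRNA_ID"].notna() & (df["circRNA_ID"] != derived)
    if mismatch.any():
        warnings.warn(
            f"{path}: {int(mismatch.sum())} circRNA_ID value(s) disagree with coordinates; "
            "trusting coordinates",
            stacklevel=2,
        )
    df["event_id"] = derived

    key = ["chrom", "start", "end", "strand"]
    if df.duplicated(key).any():
        n_dup = int(df.duplicated(key).sum())
        warnings.warn(f"{path}: {n_dup} duplicate back-splice row(s); counts summed", stacklevel=2)
        df = (
            df.groupby(key, as_index=False, sort=False)
            .agg({"event_id": "first", "gene_id": "first", "count": "sum"})
        )
    df["sample_id"] = sample_id
    return df[["event_id", "chrom", "start", "end", "strand", "gene_id", "sample_id", "count"]]


def merge_sample_tables(
    per_sample: Mapping[str, pd.DataFrame] | Iterable[tuple[str, pd.DataFrame]],
    lib_sizes: Mapping[str, int],
) -> JunctionCountTable:
    """Collect per-sample back-splice records into one count matrix.

    ``per_sample`` maps sample id to the records returned by
    `read_ciri_table` (a mapping, or (sample_id, records) pairs). The
    event set is the union across samples; an event absent from a
    sample gets count 0. Events are ordered by (chrom, start, end,
    strand), independent of input row order.
    """
    pairs = list(per_sample.items()) if isinstance(per_sample, Mapping) else list(per_sample)
    if not pairs:
        raise ValueError("at least one sample required")
    samples = [sid for sid, _ in pairs]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample id")

    frames = []
    for sid, recs in pairs:
        recs = recs.copy()
        recs["sample_id"] = sid
        frames.append(recs)
    allrec = pd.concat(frames, ignore_index=True)

    events = (
        allrec[["event_id", "chrom", "start", "end", "strand", "gene_id"]]
        .drop_duplicates(subset=["chrom", "start", "end", "strand"])
        .sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
        .set_index("event_id")
    )
    counts = (
        allrec.pivot_table(
            index="event_id", columns="sample_id", values="count", aggfunc="sum", fill_value=0.0
        )
        .reindex(index=events.index, columns=samples, fill_value=0.0)
    )
    counts.columns.name = None
    sizes = pd.Series({s: int(lib_sizes[s]) for s in samples})
    return JunctionCountTable(events=events, counts=counts, normalized=False, lib_sizes=sizes)


# ---------------------------------------------------------------------------
# linear splice junctions
# ---------------------------------------------------------------------------

_STAR_STRAND = {0: ".", 1: "+", 2: "-"}


def read_linear_junctions(
    path: str | Path,
    dialect: str = "generic",
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Read linear splice-junction counts into the generic schema.

    ``generic``: TSV with header ``chrom, donor_pos, acceptor_pos,
    strand, sample_id, count``.

    ``star_sj``: headerless STAR ``SJ.out.tab`` (chrom, intron start,
    intron end, strand code 0/1/2, motif, annotated, unique reads,
    multi reads). Donor/acceptor are the exonic positions flanking the
    intron (intron_start - 1 and intron_end + 1); the uniquely-mapped
    read count is used and multi-mapping reads are ignored.
    ``sample_id`` is required since STAR files carry none.
    """
    if dialect == "generic":
        df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
        missing = [c for c in LINEAR_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing linear-junction column(s): {', '.join(missing)}")
        df = df[LINEAR_COLUMNS].copy()
    elif dialect == "star_sj":
        if sample_id is None:
            raise ValueError("star_sj dialect requires sample_id")
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=[
                "chrom",
                "intron_start",
                "intron_end",
                "strand_code",
                "motif",
                "annotated",
                "unique_reads",
                "multi_reads",
            ],
        )
        bad = ~raw["strand_code"].isin(_STAR_STRAND)
        if bad.any():
            raise FormatError(
                f"{path}: malformed STAR strand code {raw.loc[bad, 'strand_code'].iloc[0]!r}"
            )
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"].astype(str),
                "donor_pos": raw["intron_start"].astype(int) - 1,
                "acceptor_pos": raw["intron_end"].astype(int) + 1,
                "strand": raw["strand_code"].map(_STAR_STRAND),
                "sample_id": sample_id,
                "count": raw["unique_reads"].astype(int),
            }
        )
    else:
        raise ValueError(f"unknown linear-junction dialect {dialect!r}")

    df["donor_pos"] = df["donor_pos"].astype(int)
    df["acceptor_pos"] = df["acceptor_pos"].astype(int)
    df["count"] = df["count"].astype(float)
    if (df["count"] < 0).any():
        raise FormatError(f"{path}: negative junction count")
    if (df["donor_pos"] == df["acceptor_pos"]).any():
        raise FormatError(f"{path}: donor_pos equals acceptor_pos")
    bad_strand = ~df["strand"].isin(VALID_STRANDS)
    if bad_strand.any():
        raise FormatError(f"{path}: invalid strand {df.loc[bad_strand, 'strand'].iloc[0]!r}")
    return df


# ---------------------------------------------------------------------------
# package-native tables
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, group, mrc_megascore, mirs_stage, ...).

    Group labels must be exactly ``case``/``control``; sample ids must
    be unique. Extra columns pass through untouched.
    """
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: metadata missing column {col!r}")
    bad = set(df["group"].dropna()) - VALID_GROUPS
    if bad:
        raise FormatError(f"{path}: unknown group label(s) {sorted(bad)}; expected case/control")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id in metadata")
    for col in ("mrc_megascore", "mirs_stage", "lib_size"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read long-format qPCR Ct records.

    Missing or non-numeric Ct values are dropped per record (never
    imputed) with a warning stating how many were lost; Ct outside the
    plausible window (default 5-40 cycles) is a format error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_VALUES, keep_default_na=False)
    missing = [c for c in ("target_id", "isoform", "sample_id", "ct") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing Ct column(s): {', '.join(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").fillna(1).astype(int)
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    n_bad = int(df["ct"].isna().sum())
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} record(s) with missing Ct", stacklevel=2)
        logger.info("read_ct_table(%s): dropped %d missing-Ct records", path, n_bad)
        df = df[df["ct"].notna()]
    bad_iso = set(df["isoform"]) - VALID_ISOFORMS
    if bad_iso:
        raise FormatError(f"{path}: unknown isoform class(es) {sorted(bad_iso)}")
    lo, hi = CT_WINDOW
    out = (df["ct"] < lo) | (df["ct"] > hi)
    if out.any():
        raise FormatError(f"{path}: Ct outside plausible window [{lo}, {hi}]")
    key = ["target_id", "isoform", "sample_id", "replicate"]
    if df.duplicated(key).any():
        raise FormatError(f"{path}: duplicate (target, isoform, sample, replicate) records")
    return df[CT_COLUMNS].reset_index(drop=True)


def read_splicing_table(path: str | Path) -> pd.DataFrame:
    """Read splicing records (band intensity pairs and/or percentages)."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    missing = [c for c in ("event_name", "direction", "sample_id") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing splicing column(s): {', '.join(missing)}")
    bad = set(df["direction"]) - VALID_DIRECTIONS
    if bad:
        raise FormatError(f"{path}: unknown splicing direction(s) {sorted(bad)}")
    for col in ("incl_intensity", "excl_intensity", "percent"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="raise")
    both_zero = (df["incl_intensity"] == 0) & (df["excl_intensity"] == 0)
    no_percent = df["percent"].isna()
    if (both_zero & no_percent).any():
        raise FormatError(f"{path}: zero/zero band intensities without a percent value")
    return df[SPLICING_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format=_FLOAT_FMT)


def write_linear_junctions(df: pd.DataFrame, path: str | Path) -> None:
    out = df[LINEAR_COLUMNS].copy()
    out["count"] = out["count"].map(lambda v: int(v) if float(v).is_integer() else v)
    _write_tsv(out, path)


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df, path)


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[CT_COLUMNS], path)


def write_splicing_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(df[SPLICING_COLUMNS], path)


def write_junction_counts(table: JunctionCountTable, path: str | Path) -> None:
    """Write a back-splice count matrix as one wide TSV.

    Event annotation columns come first, then one count column per
    sample. Library sizes travel in the sample metadata table, not
    here.
    """
    wide = table.events.join(table.counts)
    cols = ["chrom", "start", "end", "strand", "gene_id"] + table.samples
    wide = wide[cols]
    if not table.normalized:
        wide[table.samples] = wide[table.samples].astype(int)
    wide.index.name = "event_id"
    _write_tsv(wide, path, index=True)


def read_junction_counts(
    path: str | Path,
    lib_sizes: Mapping[str, int] | pd.Series | None = None,
    normalized: bool = False,
) -> JunctionCountTable:
    """Read a wide back-splice count matrix written by `write_junction_counts`."""
    wide = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    meta_cols = ["event_id", "chrom", "start", "end", "strand", "gene_id"]
    missing = [c for c in meta_cols if c not in wide.columns]
    if missing:
        raise FormatError(f"{path}: missing junction-count column(s): {', '.join(missing)}")
    wide["gene_id"] = wide["gene_id"].fillna("")
    wide = wide.set_index("event_id")
    sample_cols = [c for c in wide.columns if c not in meta_cols]
    events = wide[["chrom", "start", "end", "strand", "gene_id"]]
    counts = wide[sample_cols].astype(float)
    sizes = None if lib_sizes is None else pd.Series(lib_sizes).astype(int)
    return JunctionCountTable(events=events, counts=counts, normalized=normalized, lib_sizes=sizes)


RESULTS_SCHEMA_LINE = "# circlin-results schema=1"


def write_results(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write an analysis output table with a leading schema version line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(RESULTS_SCHEMA_LINE + "\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA", float_format=_FLOAT_FMT)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results table written by `write_results`."""
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=_NA_VALUES, keep_default_na=False
    )
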