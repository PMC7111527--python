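"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are 0-based half-open (BED/bedGraph convention).
Coverage arrays handed to the estimation code are oriented 5'->3' along the
transcript, i.e. minus-strand intervals are reversed on read.  Missing values
are serialized as the token ``NA`` in every TSV.

No other module in the package parses or writes files; everything goes
through the functions here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("apakit")

NA_TOKEN = "NA"

__all__ = [
    "UTRAnnotation",
    "BedGraph",
    "ApaDataset",
    "read_utr_bed",
    "write_utr_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_bedgraph_region",
    "runs_from_array",
    "read_site_table",
    "write_site_table",
    "map_sites_to_utr",
    "read_table",
    "write_table",
    "read_result_table",
    "write_result_table",
    "read_labels",
    "write_labels",
    "read_clinical",
    "read_matrix",
    "write_matrix",
]


# ---------------------------------------------------------------------------
# 3'-UTR annotation (BED6)
# ---------------------------------------------------------------------------

@dataclass
class UTRAnnotation:
    """Per-transcript 3'-UTR intervals: the coordinate frame for everything
    downstream.

    ``table`` columns: gene_id, transcript_id, chrom, utr_start, utr_end,
    strand.  ``utr_end`` is exclusive and equals the annotated distal
    poly(A)-site boundary.  One row per gene (gene_id unique).
    """

    table: pd.DataFrame
    min_length: int = 150

    def __post_init__(self) -> None:
        t = self.table
        if t["gene_id"].duplicated().any():
            dups = t.loc[t["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_id in UTR annotation: {dups[:5]}")
        bad = t["utr_end"] <= t["utr_start"]
        if bad.any():
            raise ValueError(
                f"UTR with non-positive length: {t.loc[bad, 'gene_id'].tolist()[:5]}"
            )
        short = (t["utr_end"] - t["utr_start"]) < self.min_length
        if short.any():
            raise ValueError(
                f"UTR shorter than min_length={self.min_length}: "
                f"{t.loc[short, 'gene_id'].tolist()[:5]}"
            )
        if not t["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.table = t.reset_index(drop=True)

    @property
    def lengths(self) -> pd.Series:
        s = self.table["utr_end"] - self.table["utr_start"]
        return pd.Series(s.to_numpy(), index=self.table["gene_id"].to_numpy())

    def row(self, gene_id: str) -> pd.Series:
        hit = self.table[self.table["gene_id"] == gene_id]
        if hit.empty:
            raise KeyError(gene_id)
        return hit.iloc[0]

    def __len__(self) -> int:
        return len(self.table)


def read_utr_bed(path, min_length: int = 150) -> UTRAnnotation:
    """Read a BED6 3'-UTR annotation.

    The name field is ``gene_id|transcript_id``; a bare gene id (no pipe)
    is accepted and reused as the transcript id.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            gene_id, _, tx = name.partition("|")
            rows.append(
                dict(gene_id=gene_id, transcript_id=tx or gene_id, chrom=chrom,
                     utr_start=start_i, utr_end=end_i, strand=strand)
            )
    return UTRAnnotation(pd.DataFrame(rows), min_length=min_length)


def write_utr_bed(utrs: UTRAnnotation, path) -> None:
    with open(path, "w") as fh:
        for r in utrs.table.itertuples(index=False):
            name = f"{r.gene_id}|{r.transcript_id}"
            fh.write(f"{r.chrom}\t{r.utr_start}\t{r.utr_end}\t{name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

@dataclass
class BedGraph:
    """In-memory bedGraph: per-chromosome sorted (starts, ends, values)."""

    chroms: dict = field(default_factory=dict)

    def region(self, chrom: str, start: int, end: int, strand: str = "+") -> np.ndarray:
        """Per-base depth over [start, end); bases covered by no record are 0.

        Minus strand returns the reversed array (transcript 5'->3').
        """
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        out = np.zeros(end - start, dtype=float)
        rec = self.chroms.get(chrom)
        if rec is not None:
            starts, ends, values = rec
            # records are sorted and non-overlapping; first candidate is the
            # first record ending after the query start
            i = int(np.searchsorted(ends, start, side="right"))
            n = len(starts)
            while i < n and starts[i] < end:
                a = max(int(starts[i]) - start, 0)
                b = min(int(ends[i]) - start, end - start)
                if b > a:
                    out[a:b] = values[i]
                i += 1
        if strand == "-":
            out = out[::-1].copy()
        elif strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return out


def read_bedgraph(path) -> BedGraph:
    """Parse a bedGraph file into per-chromosome arrays.

    Raises a parse error carrying the 1-based line number on malformed lines
    and on negative coverage values.
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except Exception:
        _bedgraph_report_bad_line(path)  # raises with a line number
        raise
    if df["value"].isna().any() or (df["value"] < 0).any():
        _bedgraph_report_bad_line(path)
    bg = BedGraph()
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        bg.chroms[str(chrom)] = (
            sub["start"].to_numpy(), sub["end"].to_numpy(), sub["value"].to_numpy()
        )
    return bg


def _bedgraph_report_bad_line(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            ok = len(parts) >= 4
            if ok:
                try:
                    int(parts[1]); int(parts[2])
                    v = float(parts[3])
                    ok = np.isfinite(v) and v >= 0
                except ValueError:
                    ok = False
            if not ok:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line: {line!r}")


def read_bedgraph_region(source, chrom: str, start: int, end: int,
                         strand: str = "+") -> np.ndarray:
    """Per-base coverage over a UTR interval from a bedGraph file or object."""
    bg = source if isinstance(source, BedGraph) else read_bedgraph(source)
    return bg.region(chrom, start, end, strand)


def runs_from_array(values: np.ndarray, chrom: str, offset: int) -> list:
    """Run-length encode a per-base array into bedGraph records.

    Zero runs are omitted (bedGraph leaves uncovered bases implicit).
    """
    values = np.asarray(values)
    if values.size == 0:
        return []
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.size]))
    out = []
    for a, b in zip(starts, ends):
        v = values[a]
        if v != 0:
            out.append((chrom, offset + int(a), offset + int(b), v))
    return out


def write_bedgraph(records, path) -> None:
    """Write (chrom, start, end, value) records as a bedGraph file."""
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            v = int(value) if float(value).is_integer() else value
            fh.write(f"{chrom}\t{start}\t{end}\t{v}\n")


# ---------------------------------------------------------------------------
# miRNA site table (TargetScan-style)
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["mirna_family", "gene_id", "chrom", "site_start", "site_end",
                "cwcs", "conserved_flag"]


def map_sites_to_utr(sites: pd.DataFrame, utrs: UTRAnnotation) -> pd.DataFrame:
    """Intersect genomic miRNA sites with annotated UTRs and attach
    strand-aware UTR-relative offsets.

    Plus strand: offset = genomic - utr_start.  Minus strand reflects the
    frame so offset 0 is the transcript 5' end of the UTR:
    offset_start = utr_end - site_end, offset_end = utr_end - site_start.
    Sites not fully inside their gene's UTR (or naming an unknown gene) are
    dropped; the drop count is logged and stored in ``df.attrs["n_dropped"]``.
    """
    if (sites["cwcs"] > 0).any():
        bad = sites.loc[sites["cwcs"] > 0].iloc[0]
        raise ValueError(
            "cwcs must be <= 0 (context++ scores are repression weights); "
            f"got {bad['cwcs']} for {bad['mirna_family']}/{bad['gene_id']}"
        )
    ann = utrs.table.set_index("gene_id")
    known = sites["gene_id"].isin(ann.index)
    n_unknown = int((~known).sum())
    if n_unknown:
        log.warning("site table: %d sites name genes absent from the UTR "
                    "annotation; dropped", n_unknown)
    sub = sites[known].copy()
    st = ann.loc[sub["gene_id"], "utr_start"].to_numpy()
    en = ann.loc[sub["gene_id"], "utr_end"].to_numpy()
    strand = ann.loc[sub["gene_id"], "strand"].to_numpy()
    chrom_ok = sub["chrom"].to_numpy() == ann.loc[sub["gene_id"], "chrom"].to_numpy()
    inside = chrom_ok & (sub["site_start"].to_numpy() >= st) & (sub["site_end"].to_numpy() <= en)
    n_outside = int((~inside).sum())
    plus = strand == "+"
    off_start = np.where(plus, sub["site_start"].to_numpy() - st, en - sub["site_end"].to_numpy())
    off_end = np.where(plus, sub["site_end"].to_numpy() - st, en - sub["site_start"].to_numpy())
    sub["utr_offset_start"] = off_start
    sub["utr_offset_end"] = off_end
    sub["conserved"] = sub["conserved_flag"].astype(bool)
    out = sub[inside].reset_index(drop=True)
    n_dropped = n_unknown + n_outside
    if n_outside:
        log.info("site table: %d sites fall outside their UTR; dropped", n_outside)
    out.attrs["n_dropped"] = n_dropped
    return out


def read_site_table(path, utrs: UTRAnnotation) -> pd.DataFrame:
    """Read a conserved miRNA site TSV and map it into UTR coordinates."""
    df = read_table(path)
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return map_sites_to_utr(df, utrs)


def write_site_table(sites: pd.DataFrame, path) -> None:
    write_table(sites[SITE_COLUMNS], path)


# ---------------------------------------------------------------------------
# generic TSV tables and matrices
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    """Write any pipeline result table as TSV with NA for missing values."""
    table.to_csv(path, sep="\t", index=index, na_rep=NA_TOKEN)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False,
                       index_col=index_col)


# spec-facing aliases: every result table round-trips through these
write_result_table = write_table


def read_result_table(path) -> pd.DataFrame:
    return read_table(path)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Genes-by-samples (or families-by-samples) matrix, first column = row id."""
    write_table(matrix.rename_axis(index="row_id"), path, index=True)


def read_matrix(path) -> pd.DataFrame:
    df = read_table(path, index_col=0)
    df.index.name = None
    return df


def write_labels(labels: pd.Series, path) -> None:
    df = pd.DataFrame({"sample_id": labels.index, "condition": labels.to_numpy()})
    write_table(df, path)


def read_labels(path) -> pd.Series:
    df = read_table(path)
    lab = pd.Series(df["condition"].to_numpy(), index=df["sample_id"].to_numpy())
    bad = set(lab.unique()) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"labels must be 'tumor'/'normal'; got {sorted(bad)}")
    return lab


CLINICAL_COLUMNS = ["sample_id", "time", "event", "age", "sex", "race", "stage",
                    "grade", "residual_tumor", "purity"]


def read_clinical(path) -> pd.DataFrame:
    df = read_table(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise ValueError("clinical: survival time must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("clinical: event must be 0/1")
    ok_purity = df["purity"].isna() | df["purity"].between(0, 1)
    if not ok_purity.all():
        raise ValueError("clinical: purity must be in [0,1] or NA")
    return df


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class ApaDataset:
    """PDUI matrix plus the per-sample segment abundances behind it.

    ``pdui``, ``alpha_long`` and ``alpha_short`` are genes x samples frames
    sharing index/columns; ``labels`` maps sample -> {tumor, normal};
    ``proximal_offset`` / ``utr_length`` are per-gene (bp, transcript frame).
    """

    pdui: pd.DataFrame
    labels: pd.Series
    alpha_long: pd.DataFrame | None = None
    alpha_short: pd.DataFrame | None = None
    proximal_offset: pd.Series | None = None
    utr_length: pd.Series | None = None
    purity: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.pdui.columns) - set(self.labels.index)
        if missing:
            raise ValueError(f"labels do not cover samples: {sorted(missing)[:5]}")
        bad = set(self.labels.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"labels must be 'tumor'/'normal'; got {sorted(bad)}")
        vals = self.pdui.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out_of_range = np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9
        if vals.size and out_of_range:
            raise ValueError("PDUI entries must lie in [0, 1] or be missing")
        self.labels = self.labels.loc[self.pdui.columns]

    @property
    def tumor_samples(self) -> pd.Index:
        return self.pdui.columns[(self.labels == "tumor").to_numpy()]

    @property
    def normal_samples(self) -> pd.Index:
        return self.pdui.columns[(self.labels == "normal").to_numpy()]

    def subset_samples(self, samples) -> "ApaDataset":
        samples = pd.Index(samples)
        return ApaDataset(
            pdui=self.pdui[samples],
            labels=self.labels.loc[samples],
            alpha_long=None if self.alpha_long is None else self.alpha_long[samples],
            alpha_short=None if self.alpha_short is None else self.alpha_short[samples],
            proximal_offset=self.proximal_offset,
            utr_length=self.utr_length,
            purity=None if self.purity is None else
            self.purity.reindex(samples.intersection(self.purity.index)),
        )
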