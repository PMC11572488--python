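"""Reading, writing and assembly of methylation data structures.

This module handles the on-disk formats of the pipeline:

* simplified methylation-haplotype (mHap-style) records — tab-delimited
  lines storing, per group of identical reads, the binary CpG methylation
  string and its multiplicity;
* per-CpG beta tables (BED-like TSV: chrom, start, end, beta, coverage);
* CpG coordinate indexes (2-column TSV or BED);
* sample metadata tables (sample, age, sex, disease);
* the cross-sample :class:`MethylationMatrix` bundle (directory of TSVs
  plus a JSON manifest).

Coordinates are 0-based, half-open throughout (BED convention); a CpG site
is the 2-bp dyad ``[start, start+2)``.  A coverage of zero means "not
observed": the corresponding beta is stored as NaN and excluded from all
downstream statistics, never treated as 0% methylation.
"""

from __future__ import annotations

import gzip
import io
import json
import os
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MhapRecord",
    "CpGIndex",
    "MethylationMatrix",
    "MhapParseError",
    "parse_mhap",
    "format_mhap",
    "beta_from_mhap",
    "read_cpg_index",
    "read_beta_table",
    "write_beta_table",
    "read_sample_table",
    "validate_sample_table",
    "assemble_matrix",
    "write_matrix",
    "read_matrix",
]

SITE_END_OFFSET = 2  # a CpG dyad occupies [start, start+2)

BETA_COLUMNS = ["chrom", "start", "end", "beta", "coverage"]


class MhapParseError(ValueError):
    """Raised when an mHap-style line or record is malformed."""


@dataclass(frozen=True)
class MhapRecord:
    """One aggregated read-level methylation haplotype.

    ``haplotype`` holds one character per consecutive reference CpG covered
    by the read group ('1' methylated, '0' unmethylated); ``count`` is the
    number of identical read-level haplotypes aggregated into the record.
    """

    chrom: str
    start: int
    end: int
    haplotype: str
    count: int
    strand: str = "*"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise MhapParseError(f"count must be >= 1, got {self.count}")
        if len(self.haplotype) < 1:
            raise MhapParseError("haplotype must be non-empty")
        if set(self.haplotype) - {"0", "1"}:
            raise MhapParseError(
                f"haplotype may contain only '0'/'1': {self.haplotype!r}"
            )
        if not self.start < self.end:
            raise MhapParseError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "*"}:
            raise MhapParseError(f"strand must be one of +, -, *: {self.strand!r}")


class CpGIndex:
    """Ordered reference CpG positions (forward strand), per chromosome.

    Positions are strictly sorted within each chromosome with no
    duplicates; lookups use binary search.
    """

    def __init__(self, positions: Mapping[str, Sequence[int]]):
        self._pos: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.asarray(sorted(set(int(p) for p in pos)), dtype=np.int64)
            if len(arr) != len(pos):
                raise ValueError(f"duplicate CpG positions on {chrom}")
            self._pos[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        if chrom not in self._pos:
            raise KeyError(f"chromosome {chrom!r} not in CpG index")
        return self._pos[chrom]

    def positions_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Index positions falling in the half-open interval [start, end)."""
        pos = self.positions(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._pos

    def __len__(self) -> int:
        return sum(len(v) for v in self._pos.values())


@dataclass
class MethylationMatrix:
    """Samples x CpG-sites beta values with a parallel coverage matrix.

    ``beta`` is an n x p float frame in [0, 1] with NaN where the site was
    not observed (coverage 0); ``coverage`` is an integer frame of the same
    shape.  Rows are sample ids, columns site keys ``chrom:start``.
    """

    beta: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.shape != self.coverage.shape:
            raise ValueError("beta and coverage must share shape")
        if not self.beta.index.equals(self.coverage.index) or not self.beta.columns.equals(
            self.coverage.columns
        ):
            raise ValueError("beta and coverage must share labels")
        if self.beta.index.has_duplicates or self.beta.columns.has_duplicates:
            raise ValueError("sample ids and site keys must be unique")
        uncovered = self.coverage.to_numpy() == 0
        observed = ~np.isnan(self.beta.to_numpy())
        if np.any(uncovered & observed):
            raise ValueError("beta must be missing (NaN) wherever coverage is 0")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sites(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_sites(self, sites: Sequence[str]) -> "MethylationMatrix":
        sites = list(sites)
        return MethylationMatrix(self.beta[sites].copy(), self.coverage[sites].copy())


def _open_text(path_or_stream, mode: str = "rt") -> IO[str]:
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream
    path = os.fspath(path_or_stream)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def parse_mhap(stream, cpg_index: CpGIndex) -> list[MhapRecord]:
    """Parse tab-delimited mHap-style lines into :class:`MhapRecord` objects.

    Each line has six columns: chrom, start, end, haplotype, count, strand.
    The haplotype length must equal the number of reference CpG positions
    in ``[start, end)`` according to ``cpg_index``.

    Parameters
    ----------
    stream
        Path (optionally .gz) or open text stream.
    cpg_index
        Reference CpG coordinates covering the records' chromosomes.

    Raises
    ------
    MhapParseError
        On a malformed line (with its line number) or a haplotype whose
        length disagrees with the index.
    """
    handle = _open_text(stream)
    records: list[MhapRecord] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise MhapParseError(
                f"line {lineno}: expected 6 tab-separated columns, got {len(fields)}"
            )
        chrom, start_s, end_s, hap, count_s, strand = fields
        try:
            start, end, count = int(start_s), int(end_s), int(count_s)
        except ValueError as exc:
            raise MhapParseError(f"line {lineno}: non-integer coordinate or count") from exc
        try:
            rec = MhapRecord(chrom, start, end, hap, count, strand)
        except MhapParseError as exc:
            raise MhapParseError(f"line {lineno}: {exc}") from exc
        if chrom not in cpg_index:
            raise MhapParseError(
                f"line {lineno}: chromosome {chrom!r} absent from CpG index"
            )
        n_sites = len(cpg_index.positions_in(chrom, start, end))
        if n_sites != len(hap):
            raise MhapParseError(
                f"line {lineno}: haplotype has {len(hap)} characters but the "
                f"CpG index holds {n_sites} positions in {chrom}:[{start}, {end})"
            )
        records.append(rec)
    return records


def format_mhap(records: Iterable[MhapRecord]) -> str:
    """Serialize records back to mHap-style lines (inverse of parsing)."""
    return "".join(
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.haplotype}\t{r.count}\t{r.strand}\n"
        for r in records
    )


def beta_from_mhap(records: Sequence[MhapRecord], cpg_index: CpGIndex) -> pd.DataFrame:
    """Per-CpG beta values and read coverage from haplotype records.

    For each reference CpG, coverage is the total read count of records
    covering it and beta is the methylated-read fraction.  CpGs covered by
    no record are omitted.  Reads are conserved: methylated + unmethylated
    counts equal coverage at every site.

    Returns a beta table (columns chrom, start, end, beta, coverage)
    sorted by chromosome then position.
    """
    meth: dict[tuple[str, int], int] = {}
    total: dict[tuple[str, int], int] = {}
    for rec in records:
        positions = cpg_index.positions_in(rec.chrom, rec.start, rec.end)
        if len(positions) != len(rec.haplotype):
            raise MhapParseError(
                f"record {rec.chrom}:{rec.start}-{rec.end} covers {len(positions)} "
                f"indexed CpGs but haplotype has {len(rec.haplotype)}"
            )
        for pos, state in zip(positions, rec.haplotype):
            key = (rec.chrom, int(pos))
            total[key] = total.get(key, 0) + rec.count
            if state == "1":
                meth[key] = meth.get(key, 0) + rec.count
    rows = [
        {
            "chrom": chrom,
            "start": pos,
            "end": pos + SITE_END_OFFSET,
            "beta": meth.get((chrom, pos), 0) / cov,
            "coverage": cov,
        }
        for (chrom, pos), cov in total.items()
    ]
    table = pd.DataFrame(rows, columns=BETA_COLUMNS)
    if len(table):
        table = table.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return table.astype({"start": np.int64, "end": np.int64, "coverage": np.int64})


def read_cpg_index(path) -> CpGIndex:
    """Read a CpG coordinate list: 2-column (chrom, pos) TSV or BED.

    With three or more columns the file is treated as BED and the second
    column (0-based start) is used as the CpG position.
    """
    handle = _open_text(path)
    positions: dict[str, list[int]] = {}
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"CpG index line {lineno}: expected >= 2 columns")
        try:
            pos = int(fields[1])
        except ValueError as exc:
            raise ValueError(f"CpG index line {lineno}: non-integer position") from exc
        positions.setdefault(fields[0], []).append(pos)
    return CpGIndex(positions)


def _validate_beta_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in BETA_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"beta table missing column {col!r}")
    table = table[BETA_COLUMNS].copy()
    bad_cov = table.index[table["coverage"] < 0]
    if len(bad_cov):
        raise ValueError(f"negative coverage at row {bad_cov[0]}")
    observed = table["coverage"] > 0
    beta = table["beta"]
    bad_beta = table.index[observed & ((beta < 0) | (beta > 1) | beta.isna())]
    if len(bad_beta):
        raise ValueError(
            f"beta outside [0, 1] at row {bad_beta[0]} "
            f"(value {table.loc[bad_beta[0], 'beta']!r})"
        )
    return table.astype({"start": np.int64, "end": np.int64, "coverage": np.int64})


def read_beta_table(path) -> pd.DataFrame:
    """Read a BED-like per-CpG beta table (header optional)."""
    handle = _open_text(path)
    first = handle.readline()
    if not first.strip():
        return pd.DataFrame(columns=BETA_COLUMNS)
    has_header = first.split("\t")[0].strip().lower() == "chrom"
    text = ("" if has_header else first) + handle.read()
    table = pd.read_csv(
        io.StringIO(text),
        sep="\t",
        header=None,
        names=BETA_COLUMNS,
        dtype={"chrom": str},
    )
    return _validate_beta_table(table)


def write_beta_table(table: pd.DataFrame, path) -> None:
    """Write a beta table as headered TSV; betas keep 6 decimals."""
    table = _validate_beta_table(pd.DataFrame(table))
    handle = _open_text(path, "wt")
    close = not hasattr(path, "write")
    try:
        table.to_csv(handle, sep="\t", index=False, float_format="%.6f")
    finally:
        if close:
            handle.close()


SEXES = {"male", "female", "unknown"}


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate per-sample metadata (columns sample, age, sex, disease).

    Returns a copy indexed by sample id. Ages must be positive; sex is one
    of male/female/unknown; disease is a free categorical vocabulary that
    conventionally includes the reference level "normal".
    """
    needed = {"sample", "age", "sex", "disease"}
    missing = needed - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    out = samples[["sample", "age", "sex", "disease"]].copy()
    out["sample"] = out["sample"].astype(str)
    if out["sample"].duplicated().any():
        dup = out["sample"][out["sample"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    out["age"] = out["age"].astype(float)
    if (out["age"] <= 0).any() or out["age"].isna().any():
        bad = out.loc[(out["age"] <= 0) | out["age"].isna(), "sample"].iloc[0]
        raise ValueError(f"sample {bad!r}: age must be a positive number of years")
    bad_sex = ~out["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValueError(
            f"sample {out.loc[bad_sex, 'sample'].iloc[0]!r}: sex must be one of {sorted(SEXES)}"
        )
    out["disease"] = out["disease"].astype(str)
    return out.set_index("sample", drop=False)


def read_sample_table(path) -> pd.DataFrame:
    """Read sample metadata TSV with header (sample, age, sex, disease)."""
    return validate_sample_table(pd.read_csv(_open_text(path), sep="\t"))


def site_key(chrom: str, start: int) -> str:
    return f"{chrom}:{int(start)}"


def assemble_matrix(
    site_tables: Mapping[str, pd.DataFrame], sample_table: pd.DataFrame
) -> MethylationMatrix:
    """Align per-sample beta tables into one cross-sample matrix.

    Columns are the union of site keys across samples, sorted by
    chromosome then position; rows follow ``sample_table`` order.  A
    (sample, site) pair absent from that sample's table gets coverage 0
    and missing beta.
    """
    sample_table = validate_sample_table(sample_table)
    if len(site_tables) < 2:
        raise ValueError("need at least 2 samples to assemble a matrix")
    unknown = set(site_tables) - set(sample_table.index)
    if unknown:
        raise ValueError(f"samples absent from metadata: {sorted(unknown)}")
    missing = set(sample_table.index) - set(site_tables)
    if missing:
        raise ValueError(f"metadata samples without beta tables: {sorted(missing)}")

    keyed: dict[str, pd.DataFrame] = {}
    all_sites: dict[str, tuple[str, int]] = {}
    for sample, table in site_tables.items():
        table = _validate_beta_table(pd.DataFrame(table))
        keys = [site_key(c, s) for c, s in zip(table["chrom"], table["start"])]
        if len(set(keys)) != len(keys):
            raise ValueError(f"sample {sample!r}: duplicate site keys")
        keyed[sample] = pd.DataFrame(
            {"beta": table["beta"].to_numpy(), "coverage": table["coverage"].to_numpy()},
            index=keys,
        )
        for k, c, s in zip(keys, table["chrom"], table["start"]):
            all_sites[k] = (c, int(s))

    ordered = sorted(all_sites, key=lambda k: all_sites[k])
    samples = list(sample_table.index)
    beta = pd.DataFrame(np.nan, index=samples, columns=ordered, dtype=float)
    coverage = pd.DataFrame(0, index=samples, columns=ordered, dtype=np.int64)
    for sample in samples:
        tbl = keyed[sample]
        beta.loc[sample, tbl.index] = tbl["beta"].to_numpy()
        coverage.loc[sample, tbl.index] = tbl["coverage"].to_numpy()
    beta.values[coverage.to_numpy() == 0] = np.nan
    return MethylationMatrix(beta, coverage)


def write_matrix(matrix: MethylationMatrix, sample_table: pd.DataFrame, outdir) -> None:
    """Serialize a matrix bundle: beta/coverage/metadata TSVs + manifest."""
    os.makedirs(outdir, exist_ok=True)
    matrix.beta.to_csv(os.path.join(outdir, "beta.tsv"), sep="\t", float_format="%.6f")
    matrix.coverage.to_csv(os.path.join(outdir, "coverage.tsv"), sep="\t")
    validate_sample_table(sample_table).to_csv(
        os.path.join(outdir, "samples.tsv"), sep="\t", index=False
    )
    manifest = {
        "format": "bsclock-matrix",
        "version": 1,
        "n_samples": matrix.shape[0],
        "n_sites": matrix.shape[1],
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_matrix(indir) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Read a matrix bundle written by :func:`write_matrix`."""
    beta = pd.read_csv(os.path.join(indir, "beta.tsv"), sep="\t", index_col=0)
    coverage = pd.read_csv(os.path.join(indir, "coverage.tsv"), sep="\t", index_col=0)
    beta.index = beta.index.astype(str)
    coverage.index = coverage.index.astype(str)
    samples = read_sample_table(os.path.join(indir, "samples.tsv"))
    matrix = MethylationMatrix(beta, coverage.astype(np.int64))
    if list(matrix.samples) != list(samples.index):
        raise ValueError("matrix rows and sample metadata disagree")
    return matrix, samples
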