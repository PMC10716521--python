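"""Readers, writers and validation for the tabular and genomic formats
the pipeline touches, plus the probe-exclusion rules applied to raw
methylation-array manifests.

All genomic coordinates are held 0-based half-open internally; probe
manifests carry 1-based positions on disk and are converted on load.
Tables are UTF-8 tab-delimited text; every writer also emits a small
``<path>.log`` sidecar recording row counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: recognised probe exclusion flags
PROBE_FLAGS = frozenset(
    {"Y_chromosome", "rs_probe", "ch_probe", "cross_reactive", "polymorphic"}
)

#: removal-report classes in priority order: a probe is counted once,
#: under the first class that applies
REMOVAL_CLASSES = (
    "detection",
    "y_chromosome",
    "rs_probe",
    "ch_probe",
    "cross_reactive_polymorphic",
)

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


@dataclass
class MethylationMatrix:
    """Beta-value matrix, probes as rows and samples as columns.

    Values are methylation fractions in [0, 1]; NaN marks missing.
    """

    beta: pd.DataFrame

    def __post_init__(self):
        if self.beta.index.has_duplicates:
            raise ValueError("duplicate probe ids in methylation matrix")
        if self.beta.columns.has_duplicates:
            raise ValueError("duplicate sample ids in methylation matrix")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"beta value out of [0,1] at probe {self.beta.index[i]!r}, "
                f"sample {self.beta.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def probe_ids(self):
        return list(self.beta.index)

    @property
    def sample_ids(self):
        return list(self.beta.columns)

    @property
    def shape(self):
        return self.beta.shape

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.beta.loc[list(probe_ids)])


@dataclass
class IntervalTrack:
    """A named set of genomic features, 0-based half-open [start, end)."""

    name: str
    features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chromosome", "start", "end", "label"]
        )
    )

    def __post_init__(self):
        df = self.features
        if len(df):
            if (df["start"] >= df["end"]).any():
                bad = df[df["start"] >= df["end"]].iloc[0]
                raise ValueError(
                    f"feature with start >= end in track {self.name!r}: "
                    f"{bad['chromosome']}:{bad['start']}-{bad['end']}"
                )
            if (df["start"] < 0).any():
                raise ValueError(f"negative coordinate in track {self.name!r}")

    def __len__(self):
        return len(self.features)


def _write_sidecar(path: Path, lines) -> None:
    Path(str(path) + ".log").write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_methylation_matrix(source) -> MethylationMatrix:
    """Read a beta matrix from TSV: header of sample ids, first column probes.

    Empty fields and "NA" are read as missing.  Out-of-range or
    non-numeric values raise with the probe/sample location.
    """
    df = pd.read_csv(source, sep="\t", index_col=0, comment="#",
                     na_values=sorted(MISSING_TOKENS), keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric methylation value: {exc}") from exc
    return MethylationMatrix(df)


def write_methylation_matrix(matrix: MethylationMatrix, path) -> None:
    path = Path(path)
    matrix.beta.to_csv(path, sep="\t", index_label="probe_id",
                       float_format="%.10g", na_rep="NA")
    _write_sidecar(path, [f"probes\t{matrix.shape[0]}",
                          f"samples\t{matrix.shape[1]}"])


def read_sample_table(source) -> pd.DataFrame:
    """Read the sample/phenotype table; requires group and/or hba1c."""
    df = pd.read_csv(source, sep="\t", na_values=sorted(MISSING_TOKENS),
                     keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("sample table must have a 'sample_id' column")
    if "group" not in df.columns and "hba1c" not in df.columns:
        raise ValueError("sample table needs at least one of group/hba1c")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    return df


def write_sample_table(samples: pd.DataFrame, path) -> None:
    path = Path(path)
    samples.to_csv(path, sep="\t", index=False, float_format="%.10g")
    _write_sidecar(path, [f"samples\t{len(samples)}"])


def read_probe_manifest(source) -> pd.DataFrame:
    """Read a probe manifest; positions on disk are 1-based, a 0-based
    ``pos0`` column is added on load.

    Columns: probe_id, chromosome, position, mean_detection_p,
    class_flags (comma-separated subset of PROBE_FLAGS, may be empty),
    optional gene_id.
    """
    df = pd.read_csv(source, sep="\t", na_values=sorted(MISSING_TOKENS),
                     keep_default_na=False)
    required = {"probe_id", "chromosome", "position", "mean_detection_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe manifest lacks column(s) {sorted(missing)}")
    if (df["position"] < 1).any():
        raise ValueError("manifest positions must be >= 1 (1-based)")
    if "class_flags" not in df.columns:
        df["class_flags"] = ""
    df["class_flags"] = df["class_flags"].fillna("")
    for flags in df["class_flags"]:
        fl = _parse_flags(flags)
        unknown = fl - PROBE_FLAGS
        if unknown:
            raise ValueError(f"unknown probe flag(s) {sorted(unknown)}")
    df["pos0"] = df["position"].astype(int) - 1
    return df


def write_probe_manifest(manifest: pd.DataFrame, path) -> None:
    path = Path(path)
    cols = [c for c in manifest.columns if c != "pos0"]
    manifest[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
    _write_sidecar(path, [f"probes\t{len(manifest)}"])


def _parse_flags(flags: str) -> set:
    if not isinstance(flags, str) or not flags.strip():
        return set()
    return {f.strip() for f in flags.split(",") if f.strip()}


def read_interval_track(source, name: str) -> IntervalTrack:
    """Read a BED3/BED4 track; coordinates stay 0-based half-open."""
    rows = []
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: non-numeric coordinate") from exc
        if start >= end:
            raise ValueError(f"BED line {lineno}: start >= end ({start} >= {end})")
        label = parts[3] if len(parts) > 3 else None
        rows.append((chrom, start, end, label))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "label"])
    return IntervalTrack(name=name, features=df)


def write_interval_track(track: IntervalTrack, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for row in track.features.itertuples(index=False):
            fields = [str(row.chromosome), str(int(row.start)), str(int(row.end))]
            if row.label is not None and not (isinstance(row.label, float) and np.isnan(row.label)):
                fields.append(str(row.label))
            fh.write("\t".join(fields) + "\n")
    _write_sidecar(path, [f"features\t{len(track)}"])


def read_deg_table(source) -> pd.DataFrame:
    """Read a differential-expression table with gene coordinates."""
    df = pd.read_csv(source, sep="\t", na_values=sorted(MISSING_TOKENS),
                     keep_default_na=False)
    required = {"gene_id", "chromosome", "start", "end",
                "log2_fold_change", "q_expression"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table lacks column(s) {sorted(missing)}")
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene with start >= end in DEG table")
    q = df["q_expression"]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q_expression outside [0, 1]")
    return df


def write_deg_table(degs: pd.DataFrame, path) -> None:
    path = Path(path)
    degs.to_csv(path, sep="\t", index=False, float_format="%.10g")
    _write_sidecar(path, [f"genes\t{len(degs)}"])


def filter_probes(manifest: pd.DataFrame, detection_threshold: float = 0.01):
    """Apply the probe-exclusion rules and report removals per class.

    Removes probes with mean detection p >= threshold and probes carrying
    any exclusion flag (Y chromosome, rs genotyping probes, ch non-CpG
    probes, cross-reactive or polymorphic probes).  Each removed probe is
    counted once, under the first matching class in REMOVAL_CLASSES order.
    Retained probes keep their input order.  An empty retained set is
    legal (callers get a report, not an exception).

    Returns
    -------
    (retained_ids, report)
        retained_ids: list of probe ids kept; report: dict of per-class
        removal counts plus "retained".
    """
    if len(manifest) == 0:
        raise ValueError("probe manifest is empty")
    report = {c: 0 for c in REMOVAL_CLASSES}
    retained = []
    for row in manifest.itertuples(index=False):
        flags = _parse_flags(row.class_flags)
        if row.mean_detection_p >= detection_threshold:
            report["detection"] += 1
        elif "Y_chromosome" in flags:
            report["y_chromosome"] += 1
        elif "rs_probe" in flags:
            report["rs_probe"] += 1
        elif "ch_probe" in flags:
            report["ch_probe"] += 1
        elif flags & {"cross_reactive", "polymorphic"}:
            report["cross_reactive_polymorphic"] += 1
        else:
            retained.append(row.probe_id)
    report["retained"] = len(retained)
    return retained, report
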