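"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions
-----------
* SEG: tab-separated ``sample, chrom, loc.start, loc.end, num.mark,
  seg.mean`` (optional extra columns ``state`` and ``fdr`` on called
  output); coordinates are probe positions, closed on both ends.  A
  probe-level profile is stored as a SEG whose rows are single-probe
  segments.
* BED: 0-based half-open ``chrom, start, end, name`` plus an optional
  ``feature_type`` column; empty intervals (start == end) are rejected.
* Matrices: TSV with feature rows and subject columns, index in the first
  column.
* GMT: pathway name, description, then member genes, tab-separated.
* Edge lists: two genes per line, tab-separated.

Malformed lines raise :class:`FileFormatError` carrying the file and line
number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FileFormatError
from .nea import GeneNetwork
from .segmentation import CnaCall, GenomicProfile, Segment

__all__ = [
    "read_probe_seg", "write_probe_seg",
    "read_seg", "write_seg",
    "read_matrix", "write_matrix",
    "read_bed", "write_bed",
    "read_gmt", "write_gmt",
    "read_edges", "write_edges",
]

SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.mark",
               "seg.mean"]


def _fail(path, lineno, msg):
    raise FileFormatError(f"{path}:{lineno}: {msg}")


def write_probe_seg(profile: GenomicProfile, path) -> None:
    """Write a probe-level profile as single-probe SEG rows sorted by
    (chrom, start)."""
    df = profile.probes.copy()
    df["sample"] = profile.subject
    out = pd.DataFrame({
        "sample": df["sample"], "chrom": df["chrom"],
        "loc.start": df["pos"], "loc.end": df["pos"],
        "num.mark": 1, "seg.mean": df["log2ratio"],
    })
    from .segmentation import natural_chrom_key
    out = out.sort_values(
        ["chrom", "loc.start"],
        key=lambda s: (s.map(natural_chrom_key) if s.name == "chrom" else s))
    out.to_csv(path, sep="\t", index=False)


def read_probe_seg(path) -> GenomicProfile:
    """Read a probe-level SEG written by :func:`write_probe_seg`."""
    df = _read_seg_frame(path)
    subjects = df["sample"].unique()
    if len(subjects) != 1:
        raise FileFormatError(f"{path}: expected a single-subject SEG")
    probes = pd.DataFrame({"chrom": df["chrom"].astype(str),
                           "pos": df["loc.start"].astype(int),
                           "log2ratio": df["seg.mean"].astype(float)})
    return GenomicProfile(subject=str(subjects[0]),
                          probes=probes.reset_index(drop=True))


def _read_seg_frame(path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[:6] != SEG_COLUMNS:
                    _fail(path, lineno,
                          f"SEG header must start with {SEG_COLUMNS}")
                continue
            if len(parts) != len(header):
                _fail(path, lineno,
                      f"expected {len(header)} fields, got {len(parts)}")
            try:
                int(parts[2]), int(parts[3]), int(parts[4])
                float(parts[5])
            except ValueError as exc:
                _fail(path, lineno, f"bad numeric field: {exc}")
            rows.append(parts)
    if header is None:
        raise FileFormatError(f"{path}: empty SEG file")
    df = pd.DataFrame(rows, columns=header)
    for col, typ in (("loc.start", int), ("loc.end", int),
                     ("num.mark", int), ("seg.mean", float)):
        df[col] = df[col].astype(typ)
    if "fdr" in df.columns:
        df["fdr"] = df["fdr"].replace("", np.nan).astype(float)
    return df


def write_seg(segments_by_subject: Mapping[str, Sequence[Segment]],
              path) -> None:
    """Write per-subject segments (or calls, with state/fdr columns)."""
    rows = []
    has_state = any(isinstance(s, CnaCall)
                    for segs in segments_by_subject.values() for s in segs)
    for subject in sorted(segments_by_subject):
        for s in segments_by_subject[subject]:
            row = {"sample": subject, "chrom": s.chrom,
                   "loc.start": s.start, "loc.end": s.end,
                   "num.mark": s.n_probes, "seg.mean": s.mean}
            if has_state:
                row["state"] = getattr(s, "state", "neutral")
                row["fdr"] = getattr(s, "fdr", np.nan)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seg(path):
    """Read a (multi-subject) SEG into subject -> list of Segment/CnaCall."""
    df = _read_seg_frame(path)
    out: dict[str, list] = {}
    for _, r in df.iterrows():
        if "state" in df.columns and r["state"] != "neutral":
            seg = CnaCall(str(r["chrom"]), int(r["loc.start"]),
                          int(r["loc.end"]), int(r["num.mark"]),
                          float(r["seg.mean"]), state=str(r["state"]),
                          fdr=float(r.get("fdr", np.nan)))
        else:
            seg = Segment(str(r["chrom"]), int(r["loc.start"]),
                          int(r["loc.end"]), int(r["num.mark"]),
                          float(r["seg.mean"]))
        out.setdefault(str(r["sample"]), []).append(seg)
    return out


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature")


def read_matrix(path) -> pd.DataFrame:
    """Feature x subject TSV; empty cells become missing values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None  # the index label is a header artifact
    return df.astype(float)


def write_bed(annotation: pd.DataFrame, path) -> None:
    """Write feature intervals as BED (0-based half-open) with the feature
    type in column 5."""
    cols = ["chrom", "start", "end"]
    out = annotation.reset_index()
    name_col = out.columns[0]
    bed = out[cols].copy()
    bed.insert(3, "name", out[name_col])
    if "feature_type" in out.columns:
        bed["feature_type"] = out["feature_type"]
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED4(+1) into a frame indexed by feature name."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                _fail(path, lineno, "BED needs at least 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                _fail(path, lineno, f"bad coordinate: {exc}")
            if end <= start:
                _fail(path, lineno,
                      f"empty or inverted interval [{start}, {end})")
            feature_type = parts[4] if len(parts) > 4 else "feature"
            rows.append((parts[3], parts[0], start, end, feature_type))
    df = pd.DataFrame(rows, columns=["feature", "chrom", "start", "end",
                                     "feature_type"])
    return df.set_index("feature")


def read_gmt(path) -> dict:
    """GMT pathway sets: name -> set of genes."""
    path = Path(path)
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, lineno,
                      "GMT needs name, description and >= 1 gene")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Sequence], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_edges(path) -> GeneNetwork:
    """Two-column edge TSV into a :class:`GeneNetwork`."""
    path = Path(path)
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                _fail(path, lineno, "edge line needs two gene ids")
            pairs.append((parts[0], parts[1]))
    return GeneNetwork.from_edges(pairs)


def write_edges(network: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        for i, j in network.edges:
            fh.write(f"{network.nodes[i]}\t{network.nodes[j]}\n")
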