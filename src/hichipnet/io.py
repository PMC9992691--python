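"""Readers and writers for the plain-text genomic formats used throughout.

All interval formats are 0-based half-open.  Matrices are exchanged either as
dense tab-separated text or as a 3-column coordinate list (bin_i, bin_j,
count).  Every writer produces byte-identical output for identical input so
that pipeline reruns can be compared by hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "signal"]


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a 5-column BED (chrom, start, end, name, signal)."""
    out = df.loc[:, [c for c in BED_COLUMNS if c in df.columns]].copy()
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, n_cols: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]] + list(df.columns[len(BED_COLUMNS):])
    return df


def write_bedpe(df: pd.DataFrame, path, extra_cols=()) -> None:
    """Write bin-pair records as BEDPE with any extra columns appended.

    ``df`` must carry chrom, bin1, bin2 and a ``bin_size`` attr or column.
    """
    bs = int(df.attrs.get("bin_size", df["bin_size"].iloc[0] if "bin_size" in df else 10000))
    out = pd.DataFrame(
        {
            "chrom1": df["chrom"],
            "start1": df["bin1"] * bs,
            "end1": (df["bin1"] + 1) * bs,
            "chrom2": df["chrom"],
            "start2": df["bin2"] * bs,
            "end2": (df["bin2"] + 1) * bs,
        }
    )
    for c in extra_cols:
        out[c] = df[c].values
    out.to_csv(path, sep="\t", index=False)


def read_bedpe(path, bin_size: int = 10000) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(
        {
            "chrom": df["chrom1"],
            "bin1": df["start1"] // bin_size,
            "bin2": df["start2"] // bin_size,
        }
    )
    for c in df.columns[6:]:
        out[c] = df[c]
    out.attrs["bin_size"] = bin_size
    return out


def write_bedgraph(chrom: str, bin_size: int, values, path) -> None:
    """Per-bin real-valued track; NaN bins are skipped."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])


def write_dense_matrix(counts: np.ndarray, path) -> None:
    np.savetxt(path, counts, fmt="%.6g", delimiter="\t")


def read_dense_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def write_coo_matrix(counts: np.ndarray, path) -> None:
    """Upper-triangle coordinate list (bin_i <= bin_j, count != 0)."""
    iu, ju = np.triu_indices_from(counts)
    vals = counts[iu, ju]
    keep = vals != 0
    pd.DataFrame({"bin_i": iu[keep], "bin_j": ju[keep], "count": vals[keep]}).to_csv(
        path, sep="\t", index=False
    )


def read_coo_matrix(path, n_bins: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    m = np.zeros((n_bins, n_bins))
    m[df["bin_i"], df["bin_j"]] = df["count"]
    m[df["bin_j"], df["bin_i"]] = df["count"]
    return m


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def update_manifest(outdir, stage: str, params: dict, outputs: list, seed: int | None) -> None:
    """Record per-stage provenance: parameters, seed, and output hashes."""
    outdir = Path(outdir)
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[stage] = {
        "params": params,
        "seed": seed,
        "outputs": {str(Path(o).relative_to(outdir)): sha256_file(o) for o in sorted(map(str, outputs))},
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
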