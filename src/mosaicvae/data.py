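"""Containers and I/O for mosaic single-cell multimodal datasets.

A mosaic dataset holds one cell x feature count matrix per modality (RNA
transcript counts, ATAC accessibility, ADT surface-protein tags), a per-cell
boolean availability mask saying which modalities were measured for which
cells, a batch label, and an optional partial cell-type label vector for
semi-supervision. Cells are aligned across modalities by barcode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

MISSING_LABEL = "__unlabeled__"
"""Sentinel for cells without a cell-type label (never a real label value)."""


@dataclass
class MosaicDataset:
    """Aligned mosaic multimodal dataset.

    Parameters
    ----------
    counts : dict of str -> ndarray
        Per-modality cell x feature non-negative count matrices, rows aligned
        by cell. Rows for cells where the modality is unavailable are ignored.
    mask : ndarray of bool, cells x modalities
        Availability mask, columns ordered like ``modalities``.
    batch : ndarray of str
        Per-cell batch label.
    labels : ndarray of str or None
        Per-cell cell-type label; ``MISSING_LABEL`` marks unlabeled cells.
    barcodes : list of str
        Cell identifiers, unique.
    feature_names : dict of str -> list of str
    """

    counts: dict[str, np.ndarray]
    mask: np.ndarray
    batch: np.ndarray
    barcodes: list[str]
    feature_names: dict[str, list[str]]
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.modalities = list(self.counts)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.batch = np.asarray(self.batch, dtype=object)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def validate(self) -> None:
        n = self.n_cells
        if len(set(self.barcodes)) != n:
            dupes = pd.Index(self.barcodes)
            dup = dupes[dupes.duplicated()].tolist()
            raise ValueError(f"duplicate barcodes: {dup[:5]}")
        if self.mask.shape != (n, len(self.modalities)):
            raise ValueError(
                f"mask shape {self.mask.shape} != ({n}, {len(self.modalities)})"
            )
        no_mod = np.where(self.mask.sum(axis=1) < 1)[0]
        if no_mod.size:
            names = [self.barcodes[i] for i in no_mod[:5]]
            raise ValueError(f"cells with zero available modalities: {names}")
        if len(self.batch) != n:
            raise ValueError("batch length mismatch")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length mismatch")
        for m, x in self.counts.items():
            x = np.asarray(x)
            if x.shape[0] != n:
                raise ValueError(f"counts[{m}] has {x.shape[0]} rows, expected {n}")
            if not np.issubdtype(x.dtype, np.number):
                raise ValueError(f"counts[{m}] is non-numeric")
            avail = self.mask[:, self.modalities.index(m)]
            sub = x[avail]
            if not np.all(np.isfinite(sub)):
                raise ValueError(f"counts[{m}] contains non-finite entries")
            if sub.size and sub.min() < 0:
                raise ValueError(f"counts[{m}] contains negative entries")
            if len(self.feature_names[m]) != x.shape[1]:
                raise ValueError(f"feature_names[{m}] length mismatch")

    def label_set(self) -> list[str]:
        """Distinct real labels (excluding the missing-label sentinel)."""
        if self.labels is None:
            return []
        return sorted({l for l in self.labels if l != MISSING_LABEL})

    def modality_index(self, m: str) -> int:
        return self.modalities.index(m)

    def available(self, m: str) -> np.ndarray:
        """Boolean vector of cells where modality `m` was measured."""
        return self.mask[:, self.modality_index(m)]


@dataclass
class PreprocessedDataset:
    """Normalized per-modality views ready for encoders and graphs."""

    views: dict[str, np.ndarray]
    provenance: dict[str, str] = field(default_factory=dict)

    def validate(self, ds: MosaicDataset) -> None:
        for m, v in self.views.items():
            avail = ds.available(m)
            if not np.all(np.isfinite(v[avail])):
                raise ValueError(f"view[{m}] has non-finite entries for available cells")


# --------------------------------------------------------------------------- IO


def _read_modality(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read one modality matrix; returns (cells x features, barcodes, features).

    Accepts an MTX file (with barcodes.tsv / features.tsv sidecars in the same
    directory, matrix stored features x cells per the 10x convention), a dense
    CSV (first column barcodes, header row features), or an .h5ad container.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        barcodes = (
            pd.read_csv(path.parent / "barcodes.tsv", header=None, sep="\t")[0]
            .astype(str)
            .tolist()
        )
        features = (
            pd.read_csv(path.parent / "features.tsv", header=None, sep="\t")[0]
            .astype(str)
            .tolist()
        )
        x = np.asarray(sparse.coo_matrix(mat).todense()).T  # features x cells on disk
        if x.shape != (len(barcodes), len(features)):
            raise ValueError(
                f"{path}: matrix shape {mat.shape} inconsistent with sidecars "
                f"({len(features)} features, {len(barcodes)} barcodes)"
            )
        return x.astype(np.float64), barcodes, features
    if path.suffix == ".csv":
        df = pd.read_csv(path, index_col=0)
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"{path}: non-numeric entries")
        return vals.astype(np.float64), df.index.astype(str).tolist(), df.columns.astype(str).tolist()
    if path.suffix == ".h5ad":
        import anndata as ad

        a = ad.read_h5ad(path)
        x = a.X
        if sparse.issparse(x):
            x = np.asarray(x.todense())
        return (
            np.asarray(x, dtype=np.float64),
            a.obs_names.astype(str).tolist(),
            a.var_names.astype(str).tolist(),
        )
    raise ValueError(f"unsupported modality file format: {path}")


def _read_annotation(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return dict(zip(df[0], df[1]))


def load_mosaic(
    paths: dict[str, str | Path],
    batch_path: str | Path | None = None,
    labels_path: str | Path | None = None,
) -> MosaicDataset:
    """Load a mosaic dataset from per-modality files aligned by barcode.

    Cell order is the union of barcodes in first-seen order across modalities;
    a cell absent from a modality file gets mask False there. `batch_path` and
    `labels_path` are two-column TSVs (barcode, value); unlisted cells get
    batch "0" / the missing-label sentinel.
    """
    per_mod: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
    order: list[str] = []
    seen: set[str] = set()
    for m, p in paths.items():
        x, bcs, feats = _read_modality(p)
        if len(set(bcs)) != len(bcs):
            ser = pd.Index(bcs)
            dup = ser[ser.duplicated()].tolist()
            raise ValueError(f"duplicate barcode in modality '{m}': {dup[:5]}")
        per_mod[m] = (x, bcs, feats)
        for b in bcs:
            if b not in seen:
                seen.add(b)
                order.append(b)

    n = len(order)
    pos = {b: i for i, b in enumerate(order)}
    counts: dict[str, np.ndarray] = {}
    feature_names: dict[str, list[str]] = {}
    mask = np.zeros((n, len(paths)), dtype=bool)
    for j, (m, (x, bcs, feats)) in enumerate(per_mod.items()):
        full = np.zeros((n, x.shape[1]), dtype=np.float64)
        idx = np.array([pos[b] for b in bcs], dtype=np.intp)
        full[idx] = x
        mask[idx, j] = True
        counts[m] = full
        feature_names[m] = feats

    batch = np.array(["0"] * n, dtype=object)
    if batch_path is not None:
        bmap = _read_annotation(batch_path)
        for b, v in bmap.items():
            if b in pos:
                batch[pos[b]] = v

    labels = None
    if labels_path is not None:
        labels = np.array([MISSING_LABEL] * n, dtype=object)
        lmap = _read_annotation(labels_path)
        for b, v in lmap.items():
            if b in pos:
                labels[pos[b]] = v

    return MosaicDataset(
        counts=counts,
        mask=mask,
        batch=batch,
        barcodes=order,
        feature_names=feature_names,
        labels=labels,
    )


def write_mosaic(ds: MosaicDataset, outdir: str | Path) -> Path:
    """Write a dataset as per-modality MTX + sidecars plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"modalities": {}, "batch": "batch.tsv"}
    for m in ds.modalities:
        mdir = outdir / m
        mdir.mkdir(exist_ok=True)
        avail = ds.available(m)
        bcs = [b for b, a in zip(ds.barcodes, avail) if a]
        x = ds.counts[m][avail]
        spio.mmwrite(mdir / "matrix.mtx", sparse.coo_matrix(x.T))
        pd.Series(bcs).to_csv(mdir / "barcodes.tsv", index=False, header=False)
        pd.Series(ds.feature_names[m]).to_csv(mdir / "features.tsv", index=False, header=False)
        manifest["modalities"][m] = str(Path(m) / "matrix.mtx")
    pd.DataFrame({"barcode": ds.barcodes, "batch": ds.batch}).to_csv(
        outdir / "batch.tsv", sep="\t", index=False, header=False
    )
    if ds.labels is not None:
        labeled = [(b, l) for b, l in zip(ds.barcodes, ds.labels) if l != MISSING_LABEL]
        pd.DataFrame(labeled).to_csv(outdir / "labels.tsv", sep="\t", index=False, header=False)
        manifest["labels"] = "labels.tsv"
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_manifest(manifest_path: str | Path) -> MosaicDataset:
    """Load a dataset previously written by :func:`write_mosaic`."""
    manifest_path = Path(manifest_path)
    man = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    paths = {m: root / p for m, p in man["modalities"].items()}
    labels_path = root / man["labels"] if "labels" in man else None
    return load_mosaic(paths, batch_path=root / man["batch"], labels_path=labels_path)


# ------------------------------------------------------------------ preprocess


def _lognorm(x: np.ndarray, avail: np.ndarray, target_sum: float) -> np.ndarray:
    out = np.zeros_like(x, dtype=np.float64)
    sums = x[avail].sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell rows left as zeros")
    scale = np.divide(target_sum, sums, out=np.zeros_like(sums), where=~zero)
    out[avail] = np.log1p(x[avail] * scale[:, None])
    return out


def _clr(x: np.ndarray, avail: np.ndarray) -> np.ndarray:
    # centered log-ratio across features, the common ADT transform
    out = np.zeros_like(x, dtype=np.float64)
    lx = np.log1p(x[avail])
    out[avail] = lx - lx.mean(axis=1, keepdims=True)
    return out


def _tfidf(x: np.ndarray, avail: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=np.float64)
    sub = x[avail]
    sums = sub.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cell rows left as zeros")
    sums[zero] = 1.0
    tf = sub / sums
    n = sub.shape[0]
    df = (sub > 0).sum(axis=0)
    idf = np.log1p(n / np.maximum(df, 1))
    out[avail] = np.log1p(tf * idf * 1e4)
    return out


DEFAULT_TRANSFORMS = {"rna": "lognorm", "adt": "lognorm", "atac": "tfidf"}


def preprocess(
    ds: MosaicDataset,
    transforms: dict[str, str] | None = None,
    target_sum: float = 1e4,
) -> PreprocessedDataset:
    """Normalize each modality for encoder input and graph construction.

    Defaults: per-cell total-count normalization + log1p for RNA and ADT,
    TF-IDF for ATAC. ADT may instead use the centered log-ratio transform via
    ``transforms={"adt": "clr"}``. Rows of unavailable cells are zeroed and
    must never be consumed downstream. Deterministic.
    """
    transforms = dict(transforms or {})
    views: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    for m in ds.modalities:
        kind = transforms.get(m, DEFAULT_TRANSFORMS.get(m, "lognorm"))
        avail = ds.available(m)
        x = np.asarray(ds.counts[m], dtype=np.float64)
        if kind == "lognorm":
            views[m] = _lognorm(x, avail, target_sum)
        elif kind == "clr":
            views[m] = _clr(x, avail)
        elif kind == "tfidf":
            views[m] = _tfidf(x, avail)
        elif kind == "none":
            views[m] = np.where(avail[:, None], x, 0.0)
        else:
            raise ValueError(f"unknown transform '{kind}' for modality '{m}'")
        provenance[m] = kind
    out = PreprocessedDataset(views=views, provenance=provenance)
    out.validate(ds)
    return out
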