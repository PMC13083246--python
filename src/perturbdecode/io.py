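"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices travel as 10x-style Matrix Market triplets (matrix.mtx with
features.tsv / barcodes.tsv sidecars, genes in rows, cells in columns);
in memory everything is an :class:`anndata.AnnData` (cells x genes).
Gene sets travel as GMT, with the ``_UP``/``_DN`` suffix convention for the
two halves of a GA signature. All writes are atomic (temp-then-rename).
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .utils import atomic_write_text

MTX_NAME = "matrix.mtx"
FEATURES_NAME = "features.tsv"
BARCODES_NAME = "barcodes.tsv"


def write_mtx(adata: ad.AnnData, directory) -> None:
    """Write an AnnData as a 10x-style MTX directory (genes x cells on disk)."""
    os.makedirs(directory, exist_ok=True)
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.coo_matrix(np.asarray(x))
    # disk convention is features x barcodes
    import io as _io

    buf = _io.BytesIO()
    spio.mmwrite(buf, x.T.tocoo())
    atomic_write_text(os.path.join(directory, MTX_NAME), buf.getvalue().decode())
    atomic_write_text(
        os.path.join(directory, FEATURES_NAME), "".join(f"{g}\n" for g in adata.var_names)
    )
    atomic_write_text(
        os.path.join(directory, BARCODES_NAME), "".join(f"{c}\n" for c in adata.obs_names)
    )


def read_mtx(directory) -> ad.AnnData:
    """Read a 10x-style MTX directory into an AnnData (cells x genes)."""
    mtx_path = os.path.join(directory, MTX_NAME)
    if not os.path.exists(mtx_path):
        raise FileNotFoundError(f"no {MTX_NAME} under {directory}")
    x = spio.mmread(mtx_path)
    genes = _read_lines(os.path.join(directory, FEATURES_NAME))
    cells = _read_lines(os.path.join(directory, BARCODES_NAME))
    if x.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {x.shape} does not match sidecars "
            f"({len(genes)} features, {len(cells)} barcodes)"
        )
    x = sparse.csr_matrix(x.T)
    if (x.data < 0).any():
        raise ValueError("count matrix contains negative entries")
    adata = ad.AnnData(X=x, obs=pd.DataFrame(index=cells), var=pd.DataFrame(index=genes))
    return adata


def _read_lines(path):
    with open(path) as fh:
        return [ln.rstrip("\n").split("\t")[0] for ln in fh if ln.strip()]


def write_gmt(sets: dict[str, list[str]], path, description: str = "perturbdecode") -> None:
    lines = []
    seen = set()
    for name, genes in sets.items():
        if name in seen:
            raise ValueError(f"duplicate gene set name: {name}")
        seen.add(name)
        lines.append("\t".join([name, description, *map(str, genes)]))
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name in GMT: {name}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def signatures_to_gmt(signatures) -> dict[str, list[str]]:
    """Serialize GA signatures using the _UP/_DN suffix convention.

    Empty halves are omitted (a signature with no down genes yields only the
    ``_UP`` line).
    """
    out: dict[str, list[str]] = {}
    for sig in signatures:
        if sig.up:
            out[f"{sig.target}_UP"] = sorted(sig.up)
        if sig.down:
            out[f"{sig.target}_DN"] = sorted(sig.down)
    return out


def gmt_to_signatures(sets: dict[str, list[str]]):
    """Inverse of :func:`signatures_to_gmt`."""
    from .perturbseq import GASignature

    targets: dict[str, dict[str, set]] = {}
    for name, genes in sets.items():
        if name.endswith("_UP"):
            targets.setdefault(name[:-3], {}).setdefault("up", set()).update(genes)
        elif name.endswith("_DN"):
            targets.setdefault(name[:-3], {}).setdefault("down", set()).update(genes)
        else:
            raise ValueError(f"gene set {name!r} lacks the _UP/_DN suffix")
    return [
        GASignature(target=t, up=frozenset(d.get("up", ())), down=frozenset(d.get("down", ())))
        for t, d in sorted(targets.items())
    ]


def write_cells_csv(meta: pd.DataFrame, path) -> None:
    atomic_write_text(path, meta.to_csv(index_label="cell_id"))


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_id")
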