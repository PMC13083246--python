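"""Shared numerics and file plumbing used across the pipeline."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (the q-value per gene).

    Monotone transform of the input p-values: sort, scale by n/rank, take the
    running minimum from the largest p down, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-d array of p-values")
    n = p.size
    if n == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def auroc(pos, neg) -> float:
    """AUROC of a score separating `pos` from `neg` (midrank tie convention).

    Equals the Mann-Whitney U statistic of the positive scores divided by
    n_pos * n_neg, hence invariant to monotone transforms of the score.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be nonempty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (pos.size * neg.size)


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def atomic_write_text(path, text: str) -> None:
    """Write text via a temp file in the same directory, then rename."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path, *, seed=None, config: dict | None = None,
                index: bool = True) -> None:
    """Write a TSV with a provenance header (version, seed, config hash)."""
    header = (
        f"# perturbdecode v{__version__}\n"
        f"# seed={seed}\n"
        f"# config_sha={config_hash(config)}\n"
    )
    atomic_write_text(path, header + df.to_csv(sep="\t", index=index))


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
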