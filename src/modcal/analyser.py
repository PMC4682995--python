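"""Post-processing of result stores: best run, posterior selection,
convergence diagnostics and trace extraction.

The functions accept either a :class:`~modcal.database.ResultStore` or
the :class:`pandas.DataFrame` returned by ``getdata()`` (so CSV files
written by earlier runs can be analysed directly).  Burn-in removal is
the caller's responsibility; :func:`drop_burn_in` is provided.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, InputError, UndefinedObjectiveError

__all__ = [
    "as_dataframe",
    "get_best",
    "get_posterior",
    "drop_burn_in",
    "split_chains",
    "gelman_rubin",
    "geweke",
    "parameter_trace",
    "plot_parameter_trace",
]


def as_dataframe(store) -> pd.DataFrame:
    """Normalize a ResultStore or DataFrame to a DataFrame."""
    df = store if isinstance(store, pd.DataFrame) else store.getdata()
    if len(df) == 0:
        raise DataError("result store is empty")
    return df


def _like_column(df: pd.DataFrame) -> str:
    if "like1" not in df.columns:
        raise DataError("result table has no like1 column")
    return "like1"


def _par_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("par")]


def get_best(store, direction: str = "maximize") -> tuple[np.ndarray, float]:
    """Parameter vector and score of the extremal run (ties: first wins)."""
    df = as_dataframe(store)
    like = df[_like_column(df)].to_numpy()
    idx = int(np.argmin(like)) if direction == "minimize" else int(np.argmax(like))
    pars = df.iloc[idx][_par_columns(df)].to_numpy(dtype=float)
    return pars, float(like[idx])


def get_posterior(store, fraction: float = 0.10,
                  direction: str = "maximize") -> pd.DataFrame:
    """GLUE-style behavioural selection: the best ``fraction`` of runs.

    Returns ceil(fraction * N) records ranked by like1; with
    ``fraction=1`` the whole store is returned.
    """
    if not 0 < fraction <= 1:
        raise InputError(f"fraction must lie in (0, 1], got {fraction}")
    df = as_dataframe(store)
    n = int(np.ceil(fraction * len(df)))
    like = df[_like_column(df)].to_numpy()
    # stable sort keeps first-encountered records ahead on ties
    key = like if direction == "minimize" else -like
    order = np.argsort(key, kind="stable")
    return df.iloc[order[:n]]


def drop_burn_in(store, fraction: float = 0.10) -> pd.DataFrame:
    """Remove the first ``fraction`` of records (warm-up phase)."""
    df = as_dataframe(store)
    skip = int(np.ceil(fraction * len(df)))
    return df.iloc[skip:]


def split_chains(store, parameter: str | None = None) -> list[np.ndarray]:
    """Per-chain draws, truncated to the shortest chain.

    With ``parameter`` given returns 1-D arrays of that parameter's
    trace per chain; otherwise (n, dim) arrays of all parameters.
    """
    df = as_dataframe(store)
    if "chain" not in df.columns:
        raise DataError("result table has no chain column")
    cols = [f"par{parameter}"] if parameter is not None else _par_columns(df)
    for c in cols:
        if c not in df.columns:
            raise DataError(f"no column {c!r} in result table")
    groups = [g[cols].to_numpy(dtype=float) for _, g in df.groupby("chain", sort=True)]
    n = min(len(g) for g in groups)
    groups = [g[-n:] for g in groups]
    if parameter is not None:
        groups = [g.ravel() for g in groups]
    return groups


def gelman_rubin(chains) -> np.ndarray:
    """Potential scale reduction factor R-hat per parameter.

    ``chains`` is (m, n) or (m, n, dim): m >= 2 chains of n >= 2 draws.
    With W the mean within-chain variance (divisor n-1), B the
    between-chain variance n*var(chain means, divisor m-1) and
    Vhat = ((n-1)/n)*W + B/n, returns sqrt(Vhat/W).  Values near 1
    indicate convergence; R-hat >= sqrt((n-1)/n) always.
    """
    arr = np.asarray(chains, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InputError("need at least 2 chains of at least 2 draws")
    m, n, _ = arr.shape
    chain_means = arr.mean(axis=1)                       # (m, dim)
    w = arr.var(axis=1, ddof=1).mean(axis=0)             # (dim,)
    b = n * chain_means.var(axis=0, ddof=1)              # (dim,)
    if np.any(w == 0):
        raise UndefinedObjectiveError(
            "within-chain variance is zero; R-hat undefined"
        )
    vhat = (n - 1) / n * w + b / n
    rhat = np.sqrt(vhat / w)
    return float(rhat[0]) if squeeze else rhat


def geweke(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke z-score comparing early and late chain segments.

    z = (mean_first - mean_last) / sqrt(var_first/n_first +
    var_last/n_last), computed over the first ``first`` and last
    ``last`` fractions with plain segment variances (not the original
    spectral-density estimate).  |z| well above 2 indicates the chain
    had not reached its stationary distribution.
    """
    x = np.asarray(chain, dtype=float).ravel()
    if x.size < 20:
        raise InputError(f"chain too short for the Geweke test: {x.size} < 20")
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise InputError("segment fractions must satisfy 0 < first, last, first+last <= 1")
    a = x[: int(np.floor(first * x.size))]
    b = x[-int(np.floor(last * x.size)):]
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    if va + vb == 0:
        if a.mean() == b.mean():
            return 0.0
        raise UndefinedObjectiveError("zero variance in both Geweke segments")
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def parameter_trace(store, parameter: str) -> np.ndarray:
    """The full trace of one parameter in evaluation order."""
    df = as_dataframe(store)
    col = f"par{parameter}"
    if col not in df.columns:
        raise DataError(f"no column {col!r} in result table")
    return df[col].to_numpy(dtype=float)


def plot_parameter_trace(store, path: str | None = None):
    """Minimal trace figure (one panel per parameter); returns the figure.

    Requires matplotlib; aesthetics are intentionally plain — the data
    tables behind each panel come from :func:`parameter_trace`.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = as_dataframe(store)
    cols = _par_columns(df)
    fig, axes = plt.subplots(len(cols), 1, figsize=(8, 2 * len(cols)),
                             squeeze=False)
    for ax, col in zip(axes.ravel(), cols):
        ax.plot(df[col].to_numpy(), lw=0.5)
        ax.set_ylabel(col)
    axes.ravel()[-1].set_xlabel("iteration")
    if path:
        fig.savefig(path, dpi=100)
    return fig
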