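"""Containers, validation, summarisation and file I/O for capture-recapture data.

A closed-population capture-recapture experiment records, for each of ``n``
distinct captured individuals, a binary capture history across ``m`` trapping
occasions together with individual covariates (e.g. sex, weight).  Only
captured individuals appear in the data: every capture history contains at
least one ``1``.

Occasions are indexed 1-based in all reported quantities (``t_first``,
``n_per_occasion``); internal arrays are ordinary 0-based numpy arrays.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CaptureHistory",
    "CaptureSummary",
    "GroupedSummary",
    "CaptureDataError",
    "load_capture_csv",
    "write_capture_csv",
    "summarize",
    "read_mark_inp",
    "write_mark_inp",
    "chipmunk_summary",
]


class CaptureDataError(ValueError):
    """Raised for malformed or invariant-violating capture-recapture input."""


@dataclass(frozen=True)
class CaptureHistory:
    """Binary individual x occasion capture matrix with per-individual covariates.

    Parameters
    ----------
    y : ndarray of shape (n, m)
        0/1 capture indicators; row i, column j is 1 iff individual i was
        caught on occasion j+1.  Every row must contain at least one capture.
    covariates : DataFrame with n rows
        Named numeric covariate columns.  Categorical covariates must be
        pre-coded numerically (e.g. sex: male = 1, female = 0).
    """

    y: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 2:
            raise CaptureDataError("capture matrix must be 2-dimensional")
        if not np.isin(y, (0, 1)).all():
            bad = y[~np.isin(y, (0, 1))].flat[0]
            raise CaptureDataError(f"occasion entries must be 0/1, found {bad!r}")
        y = y.astype(np.int8)
        if y.shape[0] and not (y.sum(axis=1) >= 1).all():
            idx = int(np.flatnonzero(y.sum(axis=1) == 0)[0])
            raise CaptureDataError(
                f"row {idx} has no captures; data may contain only captured individuals"
            )
        cov = self.covariates
        if cov is None or (isinstance(cov, pd.DataFrame) and cov.shape == (0, 0)):
            cov = pd.DataFrame(index=range(y.shape[0]))
        cov = pd.DataFrame(cov).reset_index(drop=True)
        if len(cov) != y.shape[0]:
            raise CaptureDataError(
                f"covariates have {len(cov)} rows, capture matrix has {y.shape[0]}"
            )
        if cov.shape[1] and cov.isna().any().any():
            cols = list(cov.columns[cov.isna().any()])
            raise CaptureDataError(f"missing covariate values in columns {cols}")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "covariates", cov)

    @property
    def n(self) -> int:
        """Number of distinct captured individuals."""
        return self.y.shape[0]

    @property
    def m(self) -> int:
        """Number of capture occasions."""
        return self.y.shape[1]

    def covariate_matrix(self, terms: list[str] | tuple[str, ...]) -> np.ndarray:
        """Return the (n, len(terms)) numeric matrix for the requested covariates."""
        missing = [t for t in terms if t not in self.covariates.columns]
        if missing:
            raise CaptureDataError(f"unknown covariates {missing}")
        if not terms:
            return np.empty((self.n, 0))
        return self.covariates.loc[:, list(terms)].to_numpy(dtype=float)


@dataclass(frozen=True)
class CaptureSummary:
    """Sufficient statistics of a :class:`CaptureHistory`.

    ``T`` are per-individual capture counts, ``t_first`` 1-based first-capture
    occasions, ``f`` the capture-frequency vector (f[k-1] = number of
    individuals caught exactly k times) and ``n_per_occasion`` the number of
    captures on each occasion.
    """

    T: np.ndarray
    t_first: np.ndarray
    f: np.ndarray
    n_per_occasion: np.ndarray
    n: int
    m: int
    total_captures: int


@dataclass(frozen=True)
class GroupedSummary:
    """Per-group sufficient statistics, for data published only in aggregate.

    ``groups`` maps a group label to ``(member_count, total_captures)``; an
    optional numeric code per group (``codes``) supports building a design
    matrix for a single categorical covariate.
    """

    groups: dict
    m: int
    codes: dict = field(default_factory=dict)
    n_per_occasion: np.ndarray | None = None
    f: np.ndarray | None = None

    def __post_init__(self) -> None:
        for label, (count, total) in self.groups.items():
            if count < 1 or total < count:
                raise CaptureDataError(
                    f"group {label!r}: need count >= 1 and >= 1 capture per individual"
                )

    @property
    def n(self) -> int:
        return sum(c for c, _ in self.groups.values())

    @property
    def total_captures(self) -> int:
        return sum(t for _, t in self.groups.values())


def summarize(ch: CaptureHistory) -> CaptureSummary:
    """Compute per-individual and per-occasion sufficient statistics.

    Satisfies the conservation identities sum_k k*f_k = sum_j n_per_occasion_j
    = sum_i T_i and sum_k f_k = n.
    """
    T = ch.y.sum(axis=1).astype(int)
    t_first = ch.y.argmax(axis=1) + 1  # rows are guaranteed non-empty
    f = np.bincount(T, minlength=ch.m + 1)[1:]
    return CaptureSummary(
        T=T,
        t_first=t_first,
        f=f,
        n_per_occasion=ch.y.sum(axis=0).astype(int),
        n=ch.n,
        m=ch.m,
        total_captures=int(T.sum()),
    )


# --- CSV I/O -----------------------------------------------------------------

_OCC_RE = re.compile(r"^occ_(\d+)$")


def load_capture_csv(path, covariate_names=None) -> CaptureHistory:
    """Read a capture-history CSV (occasion columns ``occ_1..occ_m`` + covariates).

    Parameters
    ----------
    path : str or file-like
    covariate_names : sequence of str, optional
        Covariates to keep.  Default: every non-occasion column.
    """
    df = pd.read_csv(path)
    occ_cols = sorted(
        (c for c in df.columns if _OCC_RE.match(c)),
        key=lambda c: int(_OCC_RE.match(c).group(1)),
    )
    if not occ_cols:
        raise CaptureDataError("no occasion columns (occ_1..occ_m) found")
    y = df[occ_cols].to_numpy()
    if not np.issubdtype(y.dtype, np.number):
        raise CaptureDataError("non-numeric entry in occasion columns")
    if covariate_names is None:
        covariate_names = [c for c in df.columns if c not in occ_cols]
    missing = [c for c in covariate_names if c not in df.columns]
    if missing:
        raise CaptureDataError(f"covariate columns {missing} not in file")
    return CaptureHistory(y=y, covariates=df[list(covariate_names)])


def write_capture_csv(ch: CaptureHistory, path) -> None:
    """Write a :class:`CaptureHistory` in the ``occ_1..occ_m`` CSV dialect."""
    df = pd.DataFrame(ch.y, columns=[f"occ_{j + 1}" for j in range(ch.m)])
    out = pd.concat([df, ch.covariates.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


# --- MARK .INP I/O -----------------------------------------------------------


def write_mark_inp(ch: CaptureHistory) -> str:
    """Render as MARK-style .INP text: ``011010 cov1 cov2 ;`` per individual."""
    lines = []
    for i in range(ch.n):
        hist = "".join(str(int(v)) for v in ch.y[i])
        covs = " ".join(repr(float(v)) for v in ch.covariates.iloc[i])
        lines.append(f"{hist} {covs} ;".replace("  ", " "))
    return "\n".join(lines) + "\n"


def read_mark_inp(text: str, covariate_names=None) -> CaptureHistory:
    """Parse MARK-style .INP text (inverse of :func:`write_mark_inp`)."""
    rows, covs = [], []
    m = None
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line:
            continue
        if not line.endswith(";"):
            raise CaptureDataError(f"line {lineno}: missing ';' terminator")
        parts = line[:-1].split()
        if not parts or not re.fullmatch(r"[01]+", parts[0]):
            raise CaptureDataError(f"line {lineno}: malformed capture history")
        hist = [int(c) for c in parts[0]]
        if m is None:
            m = len(hist)
        elif len(hist) != m:
            raise CaptureDataError(
                f"line {lineno}: history length {len(hist)} != {m}"
            )
        rows.append(hist)
        covs.append([float(v) for v in parts[1:]])
    if not rows:
        raise CaptureDataError("empty INP input")
    ncov = len(covs[0])
    if any(len(c) != ncov for c in covs):
        raise CaptureDataError("inconsistent number of covariate fields")
    if covariate_names is None:
        covariate_names = [f"cov_{k + 1}" for k in range(ncov)]
    cov_df = pd.DataFrame(covs, columns=list(covariate_names)[:ncov])
    return CaptureHistory(y=np.array(rows), covariates=cov_df)


# --- Least chipmunk worked-example fixture -----------------------------------

#: Captures per occasion (n_1..n_6) for the least chipmunk livetrapping study.
CHIPMUNK_N_PER_OCCASION = (7, 15, 16, 24, 19, 7)
#: Capture frequencies f_1..f_6 (number of animals caught exactly k times).
CHIPMUNK_FREQUENCIES = (21, 12, 7, 3, 2, 0)


def chipmunk_summary() -> GroupedSummary:
    """Grouped sufficient statistics for the least chipmunk dataset.

    45 distinct animals were caught over 6 occasions (88 captures in total):
    22 males averaging 1.86 captures and 23 females averaging 2.04.  The group
    capture totals 41 and 47 are the unique integers consistent with those
    printed means and the total of 88; this is a packaged fixture of published
    aggregate statistics, not raw capture histories (individual histories and
    first-capture times were never published).
    """
    return GroupedSummary(
        groups={"male": (22, 41), "female": (23, 47)},
        m=6,
        codes={"male": 1.0, "female": 0.0},
        n_per_occasion=np.array(CHIPMUNK_N_PER_OCCASION),
        f=np.array(CHIPMUNK_FREQUENCIES),
    )
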