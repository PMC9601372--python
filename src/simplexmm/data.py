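"""Long-format longitudinal data container and the logit mean model.

A record is one (subject, visit) pair carrying a proportional response
``y`` in the open interval (0, 1), a fixed-effect covariate row ``x`` whose
leading element is the constant 1, a random-effect covariate row ``z``, and
an observation time ``t``.  The conditional mean of y given the subject's
random effect b_i satisfies

    logit(mu_ij) = x_ij' beta + z_ij' b_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "LongitudinalData",
    "linear_predictor",
    "mean_from_predictor",
    "read_long_csv",
    "write_long_csv",
]


def linear_predictor(x, z, beta, b_i):
    """eta = x' beta + z' b_i for a single record (or stacked rows)."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    beta = np.asarray(beta, dtype=float)
    b_i = np.asarray(b_i, dtype=float)
    if x.shape[-1] != beta.shape[-1]:
        raise ValueError(
            f"x has {x.shape[-1]} columns but beta has length {beta.shape[-1]}"
        )
    if z.shape[-1] != b_i.shape[-1]:
        raise ValueError(
            f"z has {z.shape[-1]} columns but b has length {b_i.shape[-1]}"
        )
    return x @ beta + (z * b_i).sum(axis=-1)


def mean_from_predictor(eta):
    """Inverse logit: mu = 1 / (1 + exp(-eta))."""
    return expit(np.asarray(eta, dtype=float))


@dataclass
class LongitudinalData:
    """Stacked long-format longitudinal dataset.

    Attributes
    ----------
    y : (N,) responses, all strictly inside (0, 1)
    X : (N, p+1) fixed-effect design, leading column of ones
    Z : (N, q) random-effect design
    subject : (N,) integer codes 0..n-1, contiguous per subject
    time : (N,) observation times
    subject_ids : original labels, position = code
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    subject: np.ndarray
    time: np.ndarray
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.subject = np.asarray(self.subject, dtype=np.intp)
        self.time = np.asarray(self.time, dtype=float)
        N = self.y.shape[0]
        if self.X.ndim != 2 or self.Z.ndim != 2:
            raise ValueError("X and Z must be 2-D arrays")
        if not (self.X.shape[0] == self.Z.shape[0] == self.subject.shape[0]
                == self.time.shape[0] == N):
            raise ValueError("y, X, Z, subject and time must have equal length")
        if np.any(~((self.y > 0.0) & (self.y < 1.0))):
            i = int(np.flatnonzero(~((self.y > 0.0) & (self.y < 1.0)))[0])
            raise ValueError(
                f"response y must lie strictly inside (0, 1); record {i} has "
                f"y={self.y[i]!r} (the simplex support is open; exact 0/1 are invalid)"
            )
        for name, arr in (("X", self.X), ("Z", self.Z), ("time", self.time)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the constant 1 (intercept)")
        codes = np.unique(self.subject)
        if codes.size == 0 or codes[0] != 0 or codes[-1] != codes.size - 1:
            raise ValueError("subject codes must be contiguous integers 0..n-1")
        if self.subject_ids is None:
            self.subject_ids = codes.copy()

    # -- shape helpers -----------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_subjects(self) -> int:
        return int(self.subject.max()) + 1

    @property
    def n_fixed(self) -> int:
        """Number of fixed-effect columns, p+1 (including the intercept)."""
        return self.X.shape[1]

    @property
    def n_random(self) -> int:
        return self.Z.shape[1]

    @property
    def visits_per_subject(self) -> np.ndarray:
        return np.bincount(self.subject, minlength=self.n_subjects)

    def eta(self, beta, b):
        """Linear predictor for all records; b is (n_subjects, q)."""
        b = np.asarray(b, dtype=float)
        return self.X @ np.asarray(beta, dtype=float) + np.einsum(
            "nq,nq->n", self.Z, b[self.subject]
        )

    def mu(self, beta, b):
        """Fitted conditional means for all records."""
        return expit(self.eta(beta, b))

    # -- conversion --------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LongitudinalData":
        """Build from a long-format frame.

        Expected columns: ``subject_id``, ``visit``, ``time``, ``y``,
        ``x_1..x_p`` and ``z_1..z_q``.  The intercept column is prepended to
        X automatically; it must not be present in the file.
        """
        required = {"subject_id", "visit", "time", "y"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required column(s): {sorted(missing)}")
        xcols = sorted(
            (c for c in df.columns if c.startswith("x_")),
            key=lambda c: int(c.split("_", 1)[1]),
        )
        zcols = sorted(
            (c for c in df.columns if c.startswith("z_")),
            key=lambda c: int(c.split("_", 1)[1]),
        )
        if not zcols:
            raise ValueError("at least one random-effect column z_1 is required")
        df = df.sort_values(["subject_id", "visit"], kind="stable")
        ids, codes = np.unique(df["subject_id"].to_numpy(), return_inverse=True)
        X = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in xcols]
        )
        Z = np.column_stack([df[c].to_numpy(dtype=float) for c in zcols])
        obj = cls(
            y=df["y"].to_numpy(dtype=float),
            X=X,
            Z=Z,
            subject=codes,
            time=df["time"].to_numpy(dtype=float),
            subject_ids=ids,
        )
        obj.x_names = ["const"] + xcols
        return obj

    def to_dataframe(self) -> pd.DataFrame:
        visit = np.concatenate(
            [np.arange(k) for k in self.visits_per_subject]
        )
        out = {
            "subject_id": np.asarray(self.subject_ids)[self.subject],
            "visit": visit,
            "time": self.time,
            "y": self.y,
        }
        for k in range(1, self.n_fixed):
            out[f"x_{k}"] = self.X[:, k]
        for k in range(self.n_random):
            out[f"z_{k + 1}"] = self.Z[:, k]
        return pd.DataFrame(out)


def read_long_csv(path) -> LongitudinalData:
    """Load a long-format CSV (see :meth:`LongitudinalData.from_dataframe`)."""
    return LongitudinalData.from_dataframe(pd.read_csv(path))


def write_long_csv(data: LongitudinalData, path) -> None:
    """Write the long-format CSV representation (intercept column dropped)."""
    data.to_dataframe().to_csv(path, index=False)


def squeeze_proportions(y, n):
    """Optional (y(N-1)+0.5)/N transform for data containing exact 0/1."""
    y = np.asarray(y, dtype=float)
    return (y * (n - 1) + 0.5) / n
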