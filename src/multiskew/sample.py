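"""Input containers for skew estimation.

Two views of the same kind of data are supported: per-individual offspring
counts paired with a single exposure time each (:class:`ReproductiveSample`),
and counts paired with an (age-at-first-observation, age-at-last-observation)
interval each (:class:`AgedSample`), which the elasticity age model converts
into effective exposures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["ReproductiveSample", "AgedSample", "SkewUndefinedError"]

# relative spread of exposure shares below which exposure counts as equal
EQUAL_EXPOSURE_RTOL = 1e-9


class SkewUndefinedError(ValueError):
    """Raised when a skew index is mathematically undefined for the input
    (e.g. no reproduction observed, R = 0)."""


def _as_counts(rs: Sequence[int]) -> np.ndarray:
    arr = np.asarray(rs)
    if arr.ndim != 1:
        raise ValueError("rs must be a 1-D sequence of counts")
    if arr.size < 2:
        raise ValueError(f"need at least 2 individuals, got N={arr.size}")
    if not np.all(np.isfinite(arr.astype(float))):
        raise ValueError("rs contains non-finite values")
    if np.any(arr < 0):
        raise ValueError("rs counts must be non-negative")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError("rs counts must be integers")
    return arr.astype(np.int64)


@dataclass(frozen=True)
class ReproductiveSample:
    """Per-individual reproductive-success counts with exposure times.

    Parameters
    ----------
    rs
        Non-negative offspring count per individual (r_i).
    exposure
        Positive exposure time per individual (t_i), any consistent unit.
        Defaults to equal exposure (all ones).
    ids
        Optional opaque labels, one per individual.
    """

    rs: np.ndarray
    exposure: np.ndarray
    ids: Optional[tuple] = None
    _shares: tuple = field(init=False, repr=False, default=())

    def __init__(self, rs, exposure=None, ids=None):
        counts = _as_counts(rs)
        if exposure is None:
            expo = np.ones(counts.size, dtype=float)
        else:
            expo = np.asarray(exposure, dtype=float)
        if expo.shape != counts.shape:
            raise ValueError(
                f"rs and exposure length mismatch: {counts.size} vs {expo.size}"
            )
        if not np.all(np.isfinite(expo)):
            raise ValueError("exposure contains non-finite values")
        if np.any(expo <= 0):
            bad = int(np.flatnonzero(expo <= 0)[0])
            raise ValueError(f"exposure must be positive (individual {bad})")
        if ids is not None:
            ids = tuple(ids)
            if len(ids) != counts.size:
                raise ValueError("ids length mismatch")
        counts.setflags(write=False)
        expo.setflags(write=False)
        object.__setattr__(self, "rs", counts)
        object.__setattr__(self, "exposure", expo)
        object.__setattr__(self, "ids", ids)

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of individuals N."""
        return int(self.rs.size)

    @property
    def total_rs(self) -> int:
        """Total offspring R = sum r_i."""
        return int(self.rs.sum())

    @property
    def total_exposure(self) -> float:
        """Total exposure T = sum t_i."""
        return float(self.exposure.sum())

    @property
    def rs_shares(self) -> np.ndarray:
        """Offspring shares r_i / R. Requires R > 0."""
        r = self.total_rs
        if r == 0:
            raise SkewUndefinedError(
                "no reproduction observed (R = 0): shares undefined"
            )
        return self.rs / r

    @property
    def exposure_shares(self) -> np.ndarray:
        """Exposure shares t_i / T."""
        return self.exposure / self.exposure.sum()

    @property
    def expected_rs(self) -> np.ndarray:
        """Expected counts under equal rates: (R/T) * t_i."""
        return self.total_rs * self.exposure_shares

    def has_equal_exposure(self, rtol: float = EQUAL_EXPOSURE_RTOL) -> bool:
        """Whether exposure shares are all 1/N within relative tolerance."""
        shares = self.exposure_shares
        spread = shares.max() - shares.min()
        return bool(spread <= rtol * shares.max())

    def require_reproduction(self) -> int:
        r = self.total_rs
        if r == 0:
            raise SkewUndefinedError(
                "no reproduction observed (R = 0): skew is undefined"
            )
        return r


@dataclass(frozen=True)
class AgedSample:
    """RS counts with observation-age intervals for the elasticity age model.

    ``age_first`` (a_i) is the age at first observation, ``age_last`` (b_i)
    the age at death or censoring; 0 <= a_i < b_i. Ages must share one time
    unit — the effective exposure b^beta - a^beta is not invariant to the
    choice of unit when beta < 1, so the unit is recorded.
    """

    rs: np.ndarray
    age_first: np.ndarray
    age_last: np.ndarray
    age_unit: str = "years"
    ids: Optional[tuple] = None

    def __init__(self, rs, age_first, age_last, age_unit="years", ids=None):
        counts = _as_counts(rs)
        a = np.asarray(age_first, dtype=float)
        b = np.asarray(age_last, dtype=float)
        if a.shape != counts.shape or b.shape != counts.shape:
            raise ValueError("rs, age_first and age_last lengths must match")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("ages contain non-finite values")
        if np.any(a < 0):
            raise ValueError("age_first must be non-negative")
        if np.any(b <= a):
            bad = int(np.flatnonzero(b <= a)[0])
            raise ValueError(
                f"age_last must exceed age_first (individual {bad})"
            )
        if ids is not None:
            ids = tuple(ids)
            if len(ids) != counts.size:
                raise ValueError("ids length mismatch")
        for name, arr in (("rs", counts), ("age_first", a), ("age_last", b)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "age_unit", str(age_unit))
        object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return int(self.rs.size)

    @property
    def total_rs(self) -> int:
        return int(self.rs.sum())

    def to_linear_exposure(self) -> ReproductiveSample:
        """Exposure as elapsed time b_i - a_i (the beta -> 1 limit)."""
        return ReproductiveSample(
            self.rs, self.age_last - self.age_first, ids=self.ids
        )
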