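"""Analytic conversions between published skew indices and M / M-check.

Published values of Nonacs' B, Ruzzante's Q and Morisita's I_sigma can be
converted to the multinomial-index scale when the sample size N and total
reproductive output R that produced them are known. These relations are
exact under the conditions in which each index is defined (equal exposure
for Q and I_sigma).
"""

from __future__ import annotations

from typing import Optional

__all__ = [
    "mcheck_from_B",
    "B_from_mcheck",
    "mcheck_from_Q",
    "Q_from_mcheck",
    "m_from_morisita",
    "morisita_from_m",
    "m_from_mcheck",
    "convert_to_m",
]


def _validate(n: int, total_rs: int, min_r: int = 1) -> None:
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if total_rs < min_r:
        raise ValueError(f"need total_rs >= {min_r}, got {total_rs}")


def mcheck_from_B(b_value: float, n: int, total_rs: int) -> float:
    """M-check = B*N + (N-1)/R."""
    _validate(n, total_rs)
    return b_value * n + (n - 1.0) / total_rs


def B_from_mcheck(mcheck: float, n: int, total_rs: int) -> float:
    """B = M-check/N - (N-1)/(R*N); inverse of :func:`mcheck_from_B`."""
    _validate(n, total_rs)
    return mcheck / n - (n - 1.0) / (total_rs * n)


def mcheck_from_Q(q_value: float, n: int, total_rs: int) -> float:
    """M-check = (N/R) ((R-1) Q + 1), valid under equal exposure."""
    _validate(n, total_rs, min_r=2)
    return n / total_rs * ((total_rs - 1.0) * q_value + 1.0)


def Q_from_mcheck(mcheck: float, n: int, total_rs: int) -> float:
    """Q = (M-check R/N - 1)/(R - 1); inverse of :func:`mcheck_from_Q`."""
    _validate(n, total_rs, min_r=2)
    return (mcheck * total_rs / n - 1.0) / (total_rs - 1.0)


def m_from_morisita(morisita_value: float, total_rs: int) -> float:
    """M = ((R-1)/R) (I_sigma - 1), exact under equal exposure.

    I_sigma = 1 (the random-allocation reference value) maps to M = 0.
    """
    if total_rs < 2:
        raise ValueError(f"need total_rs >= 2, got {total_rs}")
    return (total_rs - 1.0) / total_rs * (morisita_value - 1.0)


def morisita_from_m(m_value: float, total_rs: int) -> float:
    """I_sigma = 1 + M R/(R-1); inverse of :func:`m_from_morisita`."""
    if total_rs < 2:
        raise ValueError(f"need total_rs >= 2, got {total_rs}")
    return 1.0 + m_value * total_rs / (total_rs - 1.0)


def m_from_mcheck(mcheck: float, n: int, total_rs: int) -> float:
    """M under equal exposure: M-check minus the null term (N-1)/R."""
    _validate(n, total_rs)
    return mcheck - (n - 1.0) / total_rs


# index names accepted by convert_to_m, mapped to their M-check converters
_CONVERTERS = {
    "B": mcheck_from_B,
    "Q": mcheck_from_Q,
    "Mcheck": lambda v, n, r: v,
    "I": lambda v, n, r: v,  # I == M-check under equal exposure
}


def convert_to_m(
    index_name: str, value: float, n: int, total_rs: int
) -> tuple[Optional[float], float]:
    """Convert a published index value to the (M-check, M) pair.

    Returns ``(mcheck, m)``; for Morisita's I_sigma and Waples' Delta_I the
    conversion targets M directly (M-check would require N, which cancels),
    and M-check is reconstructed from M. Raises ``KeyError``-style
    ``ValueError`` for unsupported index names (e.g. lambda, MMP: no exact
    relation to M exists).
    """
    if index_name in _CONVERTERS:
        mcheck = _CONVERTERS[index_name](value, n, total_rs)
        return mcheck, m_from_mcheck(mcheck, n, total_rs)
    if index_name in ("Morisita", "I_sigma"):
        m = m_from_morisita(value, total_rs)
        return m + (n - 1.0) / total_rs, m
    if index_name in ("WaplesDelta", "Delta_I"):
        # Delta_I equals M under equal exposure
        return value + (n - 1.0) / total_rs, value
    raise ValueError(
        f"no exact conversion to M is available for index {index_name!r}"
    )
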