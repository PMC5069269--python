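"""Embedded reference data sets.

Two classic right-censored reliability samples, entered once and pinned
by checksum in the test suite.
"""

from __future__ import annotations

import numpy as np

from .core import LifetimeSample

__all__ = ["case1_fixture", "case2_fixture", "CASE2_RECORDS"]

# Bench test of 20 identical grinders, stopped at t = 152.7: twelve
# observed failures (the last exactly at the stopping time) and eight
# suspensions.
_CASE1_FAILURES = (
    12.5, 24.4, 58.2, 68.0, 69.1, 95.5,
    96.6, 97.0, 114.2, 123.2, 125.6, 152.7,
)
_CASE1_N_CENSORED = 8
_CASE1_END = 152.7

#: Power-transformer fleet records: (unit, installation year, failure year
#: or None if still in service at the 2008 censoring year).  100 units,
#: simulated from Weibull(alpha=35, beta=3).
CASE2_RECORDS = (
    (1, 1984, None), (2, 1990, 2001), (3, 1983, 2002), (4, 1981, 2000),
    (5, 1985, None), (6, 1991, None), (7, 1982, None), (8, 1990, None),
    (9, 1983, 1999), (10, 1992, None), (11, 1983, None), (12, 1989, None),
    (13, 1985, None), (14, 1982, None), (15, 1983, None), (16, 1981, None),
    (17, 1985, None), (18, 1981, None), (19, 1988, 2002), (20, 1983, None),
    (21, 1984, None), (22, 1989, None), (23, 1988, None), (24, 1982, None),
    (25, 1981, None), (26, 1986, None), (27, 1987, None), (28, 1990, 1997),
    (29, 1980, 1996), (30, 1980, None), (31, 1981, None), (32, 1983, 1997),
    (33, 1980, None), (34, 1984, None), (35, 1982, None), (36, 1980, None),
    (37, 1985, 2007), (38, 1993, None), (39, 1983, None), (40, 1980, None),
    (41, 1981, 2001), (42, 1989, None), (43, 1993, None), (44, 1983, None),
    (45, 1993, None), (46, 1987, None), (47, 1994, None), (48, 1985, 2007),
    (49, 1981, None), (50, 1983, 2004), (51, 1982, None), (52, 1981, None),
    (53, 1986, None), (54, 1980, 1990), (55, 1980, 1994), (56, 1982, None),
    (57, 1990, 2008), (58, 1985, None), (59, 1983, None), (60, 1982, None),
    (61, 1963, 1996), (62, 1963, 2001), (63, 1961, 1998), (64, 1961, 1992),
    (65, 1960, 1984), (66, 1964, 2004), (67, 1961, 1994), (68, 1977, 1998),
    (69, 1963, 1987), (70, 1960, 1991), (71, 1961, 1983), (72, 1964, 1995),
    (73, 1963, 1998), (74, 1961, 2001), (75, 1960, 1988), (76, 1974, 2006),
    (77, 1978, 1995), (78, 1962, 1993), (79, 1963, None), (80, 1960, 1998),
    (81, 1962, 2007), (82, 1960, 1990), (83, 1962, 1980), (84, 1961, 1981),
    (85, 1964, 1989), (86, 1964, 1987), (87, 1960, 2006), (88, 1961, 1992),
    (89, 1964, None), (90, 1963, 1991), (91, 1973, None), (92, 1964, None),
    (93, 1972, 1984), (94, 1962, 2007), (95, 1963, 1997), (96, 1964, 1987),
    (97, 1964, 2002), (98, 1971, None), (99, 1965, 1990), (100, 1962, 1994),
)
_CASE2_CENSOR_YEAR = 2008


def case1_fixture() -> LifetimeSample:
    """Grinder endurance data: N = 20, n = 12, censored at 152.7."""
    times = np.array(_CASE1_FAILURES + (_CASE1_END,) * _CASE1_N_CENSORED)
    events = np.array([1] * len(_CASE1_FAILURES) + [0] * _CASE1_N_CENSORED)
    return LifetimeSample(times=times, events=events)


def case2_fixture() -> LifetimeSample:
    """Transformer fleet data: N = 100, lifetimes in years.

    A failed unit contributes (failure year - installation year) as a
    failure; a surviving unit contributes (2008 - installation year) as a
    right-censored record.  Unit 57, recorded as failing in the censoring
    year itself, is kept as a failure exactly as tabulated.  The
    left-truncation aspect of fleet data (units installed before the
    observation window) is deliberately not modelled: the sample is
    treated as right-censored only.
    """
    times, events = [], []
    for _no, installed, failed in CASE2_RECORDS:
        if failed is None:
            times.append(_CASE2_CENSOR_YEAR - installed)
            events.append(0)
        else:
            times.append(failed - installed)
            events.append(1)
    return LifetimeSample(times=np.array(times, dtype=float), events=np.array(events))
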