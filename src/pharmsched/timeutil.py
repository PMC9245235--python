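"""Clock-time arithmetic on a single prototypical 24 h day.

All times are integer minutes since midnight in ``[0, 1440)``.  Intervals are
half-open ``[start, end)``; an interval whose end precedes its start wraps
midnight and is normalized by splitting at 00:00.
"""

from __future__ import annotations

MINUTES_PER_DAY = 1440


def parse_clock(value: str | int) -> int:
    """Parse ``"HH:MM"`` (or pass through an int) to minutes since midnight."""
    if isinstance(value, int):
        minutes = value
    elif isinstance(value, str):
        parts = value.strip().split(":")
        if len(parts) != 2:
            raise ValueError(f"invalid clock time {value!r}; expected HH:MM")
        try:
            h, m = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"invalid clock time {value!r}") from exc
        if not (0 <= h < 24 and 0 <= m < 60):
            raise ValueError(f"clock time {value!r} out of range")
        minutes = 60 * h + m
    else:
        raise TypeError(f"cannot parse clock time from {type(value).__name__}")
    if not 0 <= minutes < MINUTES_PER_DAY:
        raise ValueError(f"minutes {minutes} out of [0, 1440)")
    return minutes


def format_clock(minutes: int) -> str:
    if not 0 <= minutes < MINUTES_PER_DAY:
        raise ValueError(f"minutes {minutes} out of [0, 1440)")
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def circular_diff(a: int, b: int) -> int:
    """Shortest distance between two clock times around the 24 h circle."""
    d = abs(int(a) - int(b)) % MINUTES_PER_DAY
    return min(d, MINUTES_PER_DAY - d)


def split_interval(start: int, end: int) -> list[tuple[int, int]]:
    """Normalize a possibly midnight-wrapping ``[start, end)`` interval.

    Returns a list of non-wrapping half-open intervals.  ``start == end``
    denotes the empty interval.
    """
    if start == end:
        return []
    if start < end:
        return [(start, end)]
    # wraps midnight
    out = []
    if start < MINUTES_PER_DAY:
        out.append((start, MINUTES_PER_DAY))
    if end > 0:
        out.append((0, end))
    return out


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent non-wrapping intervals."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def complement(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Complement of a union of non-wrapping intervals within the 24 h day."""
    merged = merge_intervals(intervals)
    out = []
    cursor = 0
    for s, e in merged:
        if cursor < s:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < MINUTES_PER_DAY:
        out.append((cursor, MINUTES_PER_DAY))
    return out


def total_minutes(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def point_in_intervals(t: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= t < e for s, e in intervals)


def distance_to_intervals(t: int, intervals: list[tuple[int, int]]) -> int:
    """Circular distance (minutes) from ``t`` to the nearest allowed minute.

    Zero when ``t`` lies inside one of the intervals.  The interval end is
    exclusive, so the last allowed minute of ``[s, e)`` is ``e - 1``.
    """
    if not intervals:
        raise ValueError("no allowed intervals: distance undefined")
    best = MINUTES_PER_DAY
    for s, e in intervals:
        if s <= t < e:
            return 0
        best = min(best, circular_diff(t, s), circular_diff(t, e - 1))
    return best
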