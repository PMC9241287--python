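"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately re-derive the window rules from first principles --
day-by-day scans over calendar dates and naive linear searches over the
code registry -- without calling the implementation under test.
"""

from __future__ import annotations

import datetime as dt

GROUP_ORDER = ["Immunotherapy", "Inhibitors", "Chemotherapy", "Radiotherapy", "Study"]


def _quarter_bounds(year: int, q: int) -> tuple[dt.date, dt.date]:
    start = dt.date(year, 3 * q - 2, 1)
    if q == 4:
        end = dt.date(year, 12, 31)
    else:
        end = dt.date(year, 3 * q + 1, 1) - dt.timedelta(days=1)
    return start, end


def _quarter_key(d: dt.date) -> tuple[int, int]:
    return d.year, (d.month - 1) // 3 + 1


def _matching_entries(entries, system: str | None, code: str | None):
    if system is None or code is None:
        return []
    out = []
    for e in entries:
        if e.system.value != system:
            continue
        family = e.is_prefix or (system == "ICD10GM" and len(e.code) == 3)
        if code == e.code or (family and code.startswith(e.code)):
            out.append(e)
    return out


def brute_force_lines(patient, index_year: int, index_q: int, entries, window_days: int = 30):
    """Day-by-day derivation of first/second-line episodes.

    Returns ``(first, second)`` where each is ``None`` or a dict with
    ``start``, ``window_end``, and ``group``.
    """
    # study companion quarters
    companion_quarters = set()
    for ev in patient.events:
        if ev.kind.value != "procedure":
            continue
        sysv = ev.system.value if ev.system else None
        if any(e.role.value == "study_marker" for e in _matching_entries(entries, sysv, ev.code)):
            companion_quarters.add(_quarter_key(ev.date))

    def therapy_groups(ev) -> list[str]:
        if ev.kind.value not in ("dispensing", "procedure"):
            return []
        sysv = ev.system.value if ev.system else None
        groups = [
            e.treatment_group.value
            for e in _matching_entries(entries, sysv, ev.code)
            if e.role.value == "therapy" and e.treatment_group.value != "none"
        ]
        if "Study" in groups and _quarter_key(ev.date) not in companion_quarters:
            groups = [g for g in groups if g != "Study"]
        return groups

    def events_on(day: dt.date):
        return [ev for ev in patient.events if ev.date == day and therapy_groups(ev)]

    def episode(start: dt.date) -> dict:
        end = start + dt.timedelta(days=window_days)
        window_events = []
        day = start
        while day <= end:
            window_events.extend(events_on(day))
            day += dt.timedelta(days=1)
        present = {g for ev in window_events for g in therapy_groups(ev)}
        group = next((g for g in GROUP_ORDER if g in present), "none")
        codes = {(ev.system.value, ev.code) for ev in window_events}
        return {"start": start, "window_end": end, "group": group, "codes": codes}

    # first line: scan the index quarter and the following quarter
    q_start, _ = _quarter_bounds(index_year, index_q)
    nxt_year, nxt_q = (index_year + 1, 1) if index_q == 4 else (index_year, index_q + 1)
    _, scan_end = _quarter_bounds(nxt_year, nxt_q)
    first = None
    day = q_start
    while day <= scan_end:
        if events_on(day):
            first = episode(day)
            break
        day += dt.timedelta(days=1)
    if first is None:
        return None, None

    # second line: first therapy code after the first-line month that
    # was not billed in the first-line window
    last = max((ev.date for ev in patient.events), default=first["window_end"])
    day = first["start"] + dt.timedelta(days=window_days + 1)
    while day <= last:
        fresh = [
            ev
            for ev in events_on(day)
            if (ev.system.value, ev.code) not in first["codes"]
        ]
        if fresh:
            return first, episode(day)
        day += dt.timedelta(days=1)
    return first, None


def brute_force_stage(codes_in_index_quarter: set[str]) -> str:
    """Stage by enumerating the rule cascade over raw ICD prefixes."""
    if any(c.startswith("C78") or c.startswith("C79") for c in codes_in_index_quarter):
        return "distant_mets"
    if any(c.startswith("C77") for c in codes_in_index_quarter):
        return "lymph_node_mets"
    return "no_mets"
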