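"""Independent reference implementations used as oracles in tests.

These deliberately use a different style (index lists, fixpoint merging,
per-point evaluation) from the package code they check.
"""

from __future__ import annotations

import math


def reference_maxed_interval(times, max_begin, max_end, min_ibi, min_duration, min_count):
    """Brute-force maxed-interval burst grouping over a sorted time list."""
    times = list(times)
    n = len(times)
    events: list[list[int]] = []
    k = 0
    while k < n - 1:
        if times[k + 1] - times[k] <= max_begin:
            m = k + 1
            while m < n - 1 and times[m + 1] - times[m] <= max_end:
                m += 1
            events.append(list(range(k, m + 1)))
            k = m + 1
        else:
            k += 1

    changed = True
    while changed:
        changed = False
        out: list[list[int]] = []
        for ev in events:
            if out and times[ev[0]] - times[out[-1][-1]] < min_ibi:
                out[-1] = list(range(out[-1][0], ev[-1] + 1))
                changed = True
            else:
                out.append(list(ev))
        events = out

    result = []
    for ev in events:
        dur = times[ev[-1]] - times[ev[0]]
        if dur >= min_duration and len(ev) >= min_count:
            result.append((times[ev[0]], times[ev[-1]], [times[i] for i in ev]))
    return result


def reference_ghk_anion(cl_i, cl_o, hco3_i, hco3_o, r, temp_k):
    """Point evaluation of the anion GHK reversal, written out longhand."""
    rt_over_f = 8.314462618 * temp_k / 96485.33212
    inside = cl_i + r * hco3_i
    outside = cl_o + r * hco3_o
    return 1000.0 * rt_over_f * math.log(inside / outside)


def reference_two_ion_henderson(u_plus, u_minus, c1, c2, temp_k):
    """Closed-form junction potential for a single 1:1 salt dilution (c1 -> c2),
    oriented as solution-2 minus solution-1."""
    vt = 8.314462618 * temp_k / 96485.33212 * 1000.0
    return vt * (u_plus - u_minus) / (u_plus + u_minus) * math.log(c1 / c2)
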