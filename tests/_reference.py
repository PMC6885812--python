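"""Independent straight-line reference implementations used as test oracles.

Deliberately written with plain Python loops and no shared code with the
package, so they stay an independent check on the optimized paths.
"""

import math


def reference_detect(values, k=0.45, ddof=0, min_event_samples=1):
    """Brute-force oscillation detection on a raw trace.

    Materializes the smoothed series S (pairwise means), the derivative D
    (pairwise differences), and the threshold theta = k * SD(D), then
    scans runs explicitly: an event starts at the first sample of a run
    of D > +theta, ends at the last sample of the first following run of
    D < -theta; still-open events close at the trace end.  Returns
    (onset_frame, offset_frame) pairs on the raw trace (D index i maps
    to frame i + 1).
    """
    F = [float(v) for v in values]
    n = len(F)
    if n < 4:
        raise ValueError("need at least 4 samples")
    S = []
    for i in range(n - 1):
        S.append((F[i] + F[i + 1]) / 2.0)
    D = []
    for i in range(len(S) - 1):
        D.append(S[i + 1] - S[i])
    mean = sum(D) / len(D)
    acc = 0.0
    for d in D:
        acc += (d - mean) ** 2
    variance = acc / (len(D) - ddof)
    theta = k * math.sqrt(variance)
    if theta == 0.0:
        return []

    events = []
    state = "closed"
    start = None
    for i in range(len(D)):
        d = D[i]
        if state == "closed":
            if d > theta:
                start = i
                state = "open"
        elif state == "open":
            if d < -theta:
                state = "falling"
        else:  # falling
            if d >= -theta:
                events.append((start + 1, i - 1 + 1))
                if d > theta:  # closing sample can open the next event
                    state = "open"
                    start = i
                else:
                    state = "closed"
                    start = None
    if state == "falling":
        events.append((start + 1, len(D) - 1 + 1))
    elif state == "open":
        events.append((start + 1, n - 1))
    return [
        (a, b) for a, b in events if b - a + 1 >= min_event_samples
    ]


def reference_label_count(binary, min_area=1):
    """Count 8-connected components by explicit flood fill."""
    rows = len(binary)
    cols = len(binary[0]) if rows else 0
    seen = [[False] * cols for _ in range(rows)]
    count = 0
    for r0 in range(rows):
        for c0 in range(cols):
            if not binary[r0][c0] or seen[r0][c0]:
                continue
            area = 0
            stack = [(r0, c0)]
            seen[r0][c0] = True
            while stack:
                r, c = stack.pop()
                area += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < rows
                            and 0 <= cc < cols
                            and binary[rr][cc]
                            and not seen[rr][cc]
                        ):
                            seen[rr][cc] = True
                            stack.append((rr, cc))
            if area >= min_area:
                count += 1
    return count


def reference_anova_f(groups):
    """One-way ANOVA F by explicit sums of squares."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ss_between += len(g) * (m - grand) ** 2
        for v in g:
            ss_within += (v - m) ** 2
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)
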