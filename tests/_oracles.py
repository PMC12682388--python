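"""Independent brute-force oracles used across the test suite.

These deliberately re-derive results with naive logic (per-bin python
scans, exhaustive enumeration, closed forms, grid search) so that the
vectorised implementations are checked against a second route, not
against themselves. The ray oracle shares only the *sampling convention*
(bin-centre angles, 0.4 px float32 steps, nearest-pixel lookup, origin
quantised to 1/4 px) with the implementation; all run-finding, arc and
cap logic is plain python.
"""

from __future__ import annotations

import numpy as np

from octcfa.labels import GUIDEWIRE, LIPID, LUMEN


def ray_oracle(labels, centroid, n_bins=360, step_px=0.4, spacing_um=10.0):
    """Naive per-bin polar scan: returns (lipid_arc_deg, min_cap_um)."""
    h, w = labels.shape
    cx = round(centroid[0] * 4) / 4.0
    cy = round(centroid[1] * 4) / 4.0
    corners = [(0.0, 0.0), (0.0, h - 1.0), (w - 1.0, 0.0), (w - 1.0, h - 1.0)]
    max_r = max(np.hypot(x - cx, y - cy) for x, y in corners)
    n_steps = int(np.ceil(max_r / step_px)) + 1
    radii = np.arange(n_steps, dtype=np.float32) * np.float32(step_px)
    ang = (np.arange(n_bins, dtype=np.float32) + 0.5) * np.float32(
        2.0 * np.pi / n_bins
    )

    has_lipid = [False] * n_bins
    candidates = []  # (gap_px, bin)
    for b in range(n_bins):
        xs = cx + np.cos(ang[b]) * radii
        ys = cy + np.sin(ang[b]) * radii
        ix = np.rint(xs).astype(int)
        iy = np.rint(ys).astype(int)
        seq = []
        for k in range(n_steps):
            if 0 <= ix[k] < w and 0 <= iy[k] < h:
                seq.append(int(labels[iy[k], ix[k]]))
            else:
                seq.append(-1)
        # first contiguous lumen run
        lumen_end = None
        started = False
        for k, v in enumerate(seq):
            if v == LUMEN:
                started = True
                lumen_end = k
            elif started:
                break
        # first lipid, honouring guidewire shadowing
        first_lipid = None
        for k, v in enumerate(seq):
            if v == GUIDEWIRE:
                break
            if v == LIPID:
                first_lipid = k
                break
        if first_lipid is None:
            continue
        has_lipid[b] = True
        if lumen_end is None or first_lipid <= lumen_end:
            continue  # inconsistent bin: skipped for cap
        lp = (int(iy[first_lipid]), int(ix[first_lipid]))
        lu = (int(iy[lumen_end]), int(ix[lumen_end]))
        if max(abs(lp[0] - lu[0]), abs(lp[1] - lu[1])) <= 1:
            continue  # direct neighbours are ignored
        # also ignored when the lipid pixel neighbours *any* lumen pixel
        touches_lumen = False
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy, xx = lp[0] + dy, lp[1] + dx
                if 0 <= yy < h and 0 <= xx < w and labels[yy, xx] == LUMEN:
                    touches_lumen = True
        if touches_lumen:
            continue
        gap = float(radii[first_lipid]) - float(radii[lumen_end])
        if gap < 2.0:  # sub-2-px gaps are indistinguishable from touching
            continue
        candidates.append(gap)

    # longest circular run of lipid-positive bins
    if not any(has_lipid):
        arc = 0.0
    elif all(has_lipid):
        arc = 360.0
    else:
        best = run = 0
        for v in has_lipid + has_lipid:
            run = run + 1 if v else 0
            best = max(best, run)
        arc = min(best, n_bins) * 360.0 / n_bins

    cap = min(candidates) * spacing_um if candidates else None
    return arc, cap


def window_rule_oracle_bits(length: int, window: int = 10, k: int = 3):
    """Vectorised popcount enumeration over all 2**length qualify patterns.

    Returns a boolean array over pattern codes 0..2**length-1: True when
    some window of ``window`` consecutive positions (whole unit if shorter)
    holds >= k qualifying frames.
    """
    codes = np.arange(2**length, dtype=np.uint32)
    pop = np.zeros(1 << min(length, 10), dtype=np.uint8)
    for i in range(pop.size):
        pop[i] = bin(i).count("1")
    w = min(window, length)
    mask = np.uint32((1 << w) - 1)
    out = np.zeros(codes.size, dtype=bool)
    for s in range(length - w + 1):
        out |= pop[(codes >> np.uint32(s)) & mask] >= k
    return out


def pattern_to_bits(pattern) -> int:
    """Qualify pattern (index 0 = lowest bit) -> integer code."""
    return sum(1 << i for i, v in enumerate(pattern) if v)


def kappa_direct(a, b, c, d):
    """Cohen's kappa straight from the textbook formula."""
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    return (po - pe) / (1 - pe)


def cox_loglik_two_group(beta, times, events, exposure):
    """Written-out Cox partial log-likelihood (Efron ties) for a 0/1 covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(exposure, float)
    ll = 0.0
    for t in np.unique(times[events]):
        died = events & (times == t)
        at_risk = times >= t
        d = died.sum()
        s_x = x[died].sum()
        ll += beta * s_x
        r = np.exp(beta * x[at_risk]).sum()
        r_d = np.exp(beta * x[died]).sum()
        for j in range(d):
            ll -= np.log(r - j / d * r_d)
    return ll


def logrank_oracle(times, events, group):
    """Hand-rolled two-group log-rank chi-square."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group = np.asarray(group, bool)
    obs = exp = var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & group).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (obs - exp) ** 2 / var
    return chi2
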