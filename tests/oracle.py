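"""Independent brute-force reference implementation for tests.

Every function here is a deliberately literal, loop-by-loop transcription
of the model equations — parameter table written out by hand, sums taken
term by term with ``math`` scalars — sharing no code with the package.
The tests compare the package's vectorized implementation against these.
"""

import math

# canonical parameter rows: step -> (k_rho, k_tau, rho0, tau0)
_CANONICAL = {
    "AA": (0.2, 0.406, 0.76, -1.84),
    "AT": (0.124, 0.641, -1.39, 0.0),
    "AG": (0.077, 0.28, 3.15, -1.48),
    "AC": (0.085, 0.302, 0.91, -0.64),
    "TA": (0.064, 0.365, 5.25, 0.0),
    "TG": (0.059, 0.393, 5.95, -0.05),
    "TC": (0.097, 0.408, 3.87, -1.52),
    "GG": (0.075, 0.218, 3.86, 0.4),
    "GC": (0.057, 0.256, 0.67, 0.0),
    "CG": (0.04, 0.255, 4.25, 0.0),
}

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def full_table():
    """All 16 steps; the missing orientation of each pair gets -tau0."""
    table = dict(_CANONICAL)
    for step, (kr, kt, r0, t0) in _CANONICAL.items():
        rc = _COMP[step[1]] + _COMP[step[0]]
        if rc not in table:
            table[rc] = (kr, kt, r0, -t0)
    return table


def accumulated_twist(i, omega=34.8):
    """Half a step to the first step centre, then whole steps outward."""
    assert i != 0
    if i > 0:
        total = 0.5 * omega
        for _ in range(2, i + 1):
            total += omega
        return total
    total = -0.5 * omega
    for _ in range(-2, i - 1, -1):
        total -= omega
    return total


def _step_at(window, dyad, i):
    """Dinucleotide of step i relative to the dyad index within the window."""
    if i > 0:
        return window[dyad + i - 1 : dyad + i + 1]
    return window[dyad + i : dyad + i + 2]


def _step_indices(max_i=64):
    return [i for i in range(-max_i, max_i + 1) if i != 0]


def torque(window, alpha=579.0, omega=34.8, max_i=64):
    """F_b from the bend-angle constraint, summed term by term."""
    table = full_table()
    dyad = len(window) // 2
    numerator = alpha
    denominator = 0.0
    for i in _step_indices(max_i):
        kr, kt, r0, t0 = table[_step_at(window, dyad, i)]
        O = math.radians(accumulated_twist(i, omega))
        numerator -= r0 * math.cos(O)
        numerator -= t0 * math.sin(O)
        denominator += math.cos(O) ** 2 / kr + math.sin(O) ** 2 / kt
    return numerator / denominator


def step_energy(window, i, F_b, omega=34.8):
    table = full_table()
    dyad = len(window) // 2
    kr, kt, r0, t0 = table[_step_at(window, dyad, i)]
    O = math.radians(accumulated_twist(i, omega))
    return (F_b ** 2 / (2 * kr)) * math.cos(O) ** 2 + (F_b ** 2 / (2 * kt)) * math.sin(O) ** 2


def window_energy(window, alpha=579.0, omega=34.8, max_i=64):
    F_b = torque(window, alpha, omega, max_i)
    return sum(step_energy(window, i, F_b, omega) for i in _step_indices(max_i))


def deformed_bend_angle(window, alpha=579.0, omega=34.8, max_i=64):
    """Deform roll/tilt under F_b and sum their bend projections."""
    table = full_table()
    dyad = len(window) // 2
    F_b = torque(window, alpha, omega, max_i)
    total = 0.0
    for i in _step_indices(max_i):
        kr, kt, r0, t0 = table[_step_at(window, dyad, i)]
        O = math.radians(accumulated_twist(i, omega))
        rho = r0 + F_b * math.cos(O) / kr
        tau = t0 + F_b * math.sin(O) / kt
        total += rho * math.cos(O) + tau * math.sin(O)
    return total


def formation_potential(E, beta=1.0):
    return math.exp(-beta * E)


def potential_series(sequence, beta=1.0, alpha=579.0, omega=34.8, max_i=64):
    """S at every position; None where no full contact window exists."""
    n = len(sequence)
    out = [None] * n
    for j in range(n):
        if j - max_i < 0 or j + max_i >= n:
            continue
        window = sequence[j - max_i : j + max_i + 1]
        if any(b not in "ACGT" for b in window):
            continue
        out[j] = formation_potential(window_energy(window, alpha, omega, max_i), beta)
    return out


def occupancy_series(sequence, l=51, beta=1.0, alpha=579.0, omega=34.8, max_i=64):
    """Mean of defined S over the l-window centred at each position."""
    S = potential_series(sequence, beta, alpha, omega, max_i)
    n = len(sequence)
    half = (l - 1) // 2
    out = [None] * n
    for j in range(n):
        vals = [S[k] for k in range(max(0, j - half), min(n, j + half + 1)) if S[k] is not None]
        if vals:
            out[j] = sum(vals) / len(vals)
    return out


def spearman_rank_pearson(x, y):
    """Rank (average ranks for ties) then Pearson, all by hand."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda k: v[k])
        r = [0.0] * len(v)
        k = 0
        while k < len(v):
            j = k
            while j + 1 < len(v) and v[order[j + 1]] == v[order[k]]:
                j += 1
            avg = (k + j) / 2 + 1
            for t in range(k, j + 1):
                r[order[t]] = avg
            k = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
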