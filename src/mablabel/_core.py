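"""Compiled inner loop of the Gillespie direct method.

The jitted kernel mirrors, step for step, the pure-Python reference loop in
:mod:`mablabel.ssa_engine`: same propensity formulas, same draw order (one
uniform for the waiting time, one for the channel), same tie-breaking.  Both
consume the same Mersenne-Twister stream, so for a given seed the two
backends produce bit-identical state sequences and channel choices (waiting
times can differ by one ulp where the compiled log rounds differently); a
regression test asserts this.

Status codes returned by the kernel:

* 0 -- simulated time reached ``t_end``
* 1 -- absorbing state (total propensity zero)
* 2 -- event budget ``max_events`` exhausted
"""

import numpy as np
from numba import njit

# Change matrix, rows = channels in canonical order, cols = (A_b, A_c, A_o,
# AR, ARR, R).  Kept in sync with reaction_network by a unit test.
CHANGE_MATRIX = np.array([
    [+1, 0, 0, 0, 0, 0],   # k_2p: source -> boundary
    [-1, 0, 0, 0, 0, 0],   # k_2n: boundary -> source
    [-1, +1, 0, 0, 0, 0],  # k_1p: boundary -> cell layer
    [+1, -1, 0, 0, 0, 0],  # k_1n: cell layer -> boundary
    [0, -1, +1, 0, 0, 0],  # k_on: cell layer -> adsorbed
    [0, +1, -1, 0, 0, 0],  # k_off: adsorbed -> cell layer
    [0, 0, -1, +1, 0, -1],  # k_mp: A_o + R -> AR
    [0, 0, +1, -1, 0, +1],  # k_mn: AR -> A_o + R
    [0, 0, 0, -1, +1, -1],  # k_bp: AR + R -> ARR
    [0, 0, 0, +1, -1, +1],  # k_bn: ARR -> AR + R
], dtype=np.int64)


@njit(cache=True)
def run_direct(counts, A_s, rates, t0, t_end, snap_times, seed,
               max_events, log_capacity, change):  # pragma: no cover - jitted
    np.random.seed(seed)
    c = counts.copy()
    t = t0
    n_snap = snap_times.shape[0]
    snaps = np.zeros((n_snap, 6), dtype=np.int64)
    si = 0

    log_t = np.empty(log_capacity, dtype=np.float64)
    log_tau = np.empty(log_capacity, dtype=np.float64)
    log_ch = np.empty(log_capacity, dtype=np.int8)
    n_logged = 0
    log_overflow = False

    alpha = np.empty(10, dtype=np.float64)
    n_events = 0
    status = 0

    while True:
        if n_events >= max_events:
            status = 2
            break

        alpha[0] = rates[0] * A_s
        alpha[1] = rates[1] * c[0]
        alpha[2] = rates[2] * c[0]
        alpha[3] = rates[3] * c[1]
        alpha[4] = rates[4] * c[1]
        alpha[5] = rates[5] * c[2]
        alpha[6] = rates[6] * c[2] * c[5]
        alpha[7] = rates[7] * c[3]
        alpha[8] = rates[8] * c[3] * c[5]
        alpha[9] = rates[9] * c[4]
        total = 0.0
        for j in range(10):
            total += alpha[j]

        if total <= 0.0:
            status = 1
            break

        u1 = np.random.random()
        while u1 == 0.0:
            u1 = np.random.random()
        tau = np.log(1.0 / u1) / total
        t_next = t + tau

        # Grid points passed before the event keep the pre-event state.
        while si < n_snap and snap_times[si] < t_next:
            for k in range(6):
                snaps[si, k] = c[k]
            si += 1

        if t_next > t_end:
            t = t_end
            break

        u2 = np.random.random()
        r = u2 * total
        cum = 0.0
        ch = 9
        for j in range(10):
            cum += alpha[j]
            if cum > r:
                ch = j
                break

        for k in range(6):
            c[k] += change[ch, k]
        t = t_next
        n_events += 1

        if log_capacity > 0:
            if n_logged < log_capacity:
                log_t[n_logged] = t
                log_tau[n_logged] = tau
                log_ch[n_logged] = ch
                n_logged += 1
            else:
                log_overflow = True

    while si < n_snap:
        for k in range(6):
            snaps[si, k] = c[k]
        si += 1

    return (snaps, c, t, n_events, status,
            log_t[:n_logged], log_tau[:n_logged], log_ch[:n_logged],
            log_overflow)
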