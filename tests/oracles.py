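"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the posterior oracle
integrates the exponential-baseline posterior on a dense 2-D grid, and the
endpoint oracle is a literal nested scan of the weaning rule.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def grid_prob_hr_greater(times, events, arms, upper,
                         log_hr_sd=2.5, intercept_sd=20.0,
                         n_grid=401, half_width_sds=8.0):
    """P(HR > 1) by dense trapezoid integration over (beta, beta0).

    The model is the exponential reduction of the PH likelihood with a
    constant baseline hazard exp(beta0)/upper on [0, upper]:

        ll = sum_i [ d_i (beta0 - log U + beta a_i)
                     - exp(beta0) (t_i / U) exp(beta a_i) ]

    with N(0, log_hr_sd^2) and N(0, intercept_sd^2) priors.
    """
    t = np.asarray(times, float)
    d = np.asarray(events, float)
    a = np.asarray(arms, float)

    def logpost(beta, beta0):
        eta = beta0 + beta * a
        ll = np.sum(d * (eta - np.log(upper))) - np.sum(
            np.exp(eta) * t / upper
        )
        return (ll - 0.5 * (beta / log_hr_sd) ** 2
                - 0.5 * (beta0 / intercept_sd) ** 2)

    res = minimize(lambda th: -logpost(*th), np.array([0.0, 0.0]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10})
    b_hat, b0_hat = res.x
    # curvature-based grid half-widths
    eps = 1e-4
    h_bb = -(logpost(b_hat + eps, b0_hat) - 2 * logpost(b_hat, b0_hat)
             + logpost(b_hat - eps, b0_hat)) / eps**2
    h_00 = -(logpost(b_hat, b0_hat + eps) - 2 * logpost(b_hat, b0_hat)
             + logpost(b_hat, b0_hat - eps)) / eps**2
    sd_b = 1 / np.sqrt(max(h_bb, 1e-12))
    sd_0 = 1 / np.sqrt(max(h_00, 1e-12))
    betas = np.linspace(b_hat - half_width_sds * sd_b,
                        b_hat + half_width_sds * sd_b, n_grid)
    beta0s = np.linspace(b0_hat - half_width_sds * sd_0,
                         b0_hat + half_width_sds * sd_0, n_grid)
    lp = np.empty((n_grid, n_grid))
    for i, b in enumerate(betas):
        lp[i] = [logpost(b, b0) for b0 in beta0s]
    lp -= lp.max()
    marg_beta = logsumexp(lp, axis=1)
    w = np.exp(marg_beta)
    total = np.trapezoid(w, betas)
    pos = betas > 0
    upper_mass = np.trapezoid(np.where(pos, w, 0.0), betas)
    return float(upper_mass / total)


def scan_endpoint(rows, cap_hours=720.0,
                  ppv_modes=("invasive ventilation", "BiPAP", "CPAP", "NIV")):
    """Exhaustive-scan oracle for the primary-endpoint rule.

    ``rows`` is a list of (timestamp, channel, value) tuples for one
    encounter.  Returns (duration, censored, clock_start, ppv_applied).
    Written as plain nested loops over candidate endpoints.
    """
    rows = sorted(rows, key=lambda r: r[0])
    order_times = [r[0] for r in rows if r[1] == "powerplan_order"]
    assert len(order_times) == 1
    order = order_times[0]
    flows = [(r[0], float(r[2])) for r in rows if r[1] == "hfnc_flow_lpm"
             and r[0] >= order]
    ppvs = [r[0] for r in rows if r[1] == "resp_mode" and r[2] in ppv_modes
            and r[0] > order]

    clock = order
    applied = False
    for _ in range(len(ppvs) + 1):
        # candidate endpoints: sub-4 flows in the follow-up window never
        # followed by a >= 4 flow inside the window
        endpoint = None
        for t_e, v_e in flows:
            if not (clock < t_e < clock + cap_hours) or v_e >= 4.0:
                continue
            ok = True
            for t_l, v_l in flows:
                if t_e < t_l < clock + cap_hours and v_l >= 4.0:
                    ok = False
                    break
            if ok:
                endpoint = t_e
                break
        horizon = endpoint if endpoint is not None else clock + cap_hours
        later_ppv = [t for t in ppvs if t < horizon]
        new_clock = max(later_ppv) if later_ppv else order
        if new_clock <= clock:
            break
        clock = new_clock
        applied = True
    if endpoint is None:
        return cap_hours, True, clock, applied
    return endpoint - clock, False, clock, applied
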