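"""Independent brute-force oracles used by the test suite.

These re-derive model behaviour from first principles (explicit loops over
the grid, literal transcription of the routing rules) and must stay
independent of the implementation in ``icisim.model``.
"""

from __future__ import annotations

import numpy as np


def brute_force_rhs(T, D_act, D_m, C, P, sp, gp, drug_off=False,
                    killing_off=False):
    """Literal, loop-based right-hand side of the T-cell grid system.

    Transcribes the biological rules cell-by-cell:

    * a cell at (i, j < m) divides at its compartment's effective rate;
      both daughters land at senescence j+1, each staying in compartment i
      with probability a_i and moving to i+1 otherwise (EFF -> EXH);
    * SCM/CM division is boosted by mature DCs, EM/EFF division impaired by
      the PD-1 pressure g = (j/m) * C/(C+K_PD) * (1-B);
    * deaths at mu_i, PD-1 apoptosis kC03/kC04 * g on EM/EFF;
    * naive influx into (SCM, 0); DC two-stage kinetics; power-law tumor
      growth minus saturating killing; first-order drug elimination.
    """
    m = gp.m
    nl = m + 1
    a = [sp.a_SCM, sp.a_CM, sp.a_EM, sp.a_EFF]
    B = 0.0 if (drug_off or P <= 0) else P / (P + gp.EC50)
    dsat = D_m / (gp.K_D + D_m) if D_m > 0 else 0.0
    Cp = max(C, 0.0)
    csat_pd = Cp / (Cp + gp.K_PD)

    def g(j):
        return (j / m) * csat_pd * (1.0 - B)

    def rate(i, j):
        if j >= m or i == 4:
            return 0.0
        r = gp.p_div[i]
        if i in (0, 1):
            r *= 1.0 + gp.s_max * dsat
        else:
            r *= 1.0 - gp.eps_div * g(j)
        return r

    dT = np.zeros((5, nl))
    for i in range(5):
        for j in range(nl):
            n = T[i][j]
            r = rate(i, j)
            dT[i][j] -= r * n            # mother leaves on division
            dT[i][j] -= gp.mu[i] * n     # natural death
            if r > 0:
                stay = 2.0 * a[i] * r * n
                move = 2.0 * (1.0 - a[i]) * r * n
                dT[i][j + 1] += stay
                dT[i + 1][j + 1] += move
            if i == 2:
                dT[i][j] -= sp.kC03 * g(j) * n
            if i == 3:
                dT[i][j] -= sp.kC04 * g(j) * n
    dT[0][0] += gp.sigma_N * dsat

    dD_act = sp.rho_D * Cp / (Cp + gp.K_Cdc) - (gp.m_DC + gp.d_act) * D_act
    dD_m = gp.m_DC * D_act - gp.d_m * D_m

    dC = sp.p_C * Cp ** (2.0 / 3.0)
    if not killing_off:
        killers = sum(T[3]) + gp.phi_EM * sum(T[2])
        pool = sum(T[2]) + sum(T[3])
        if pool > 0 and killers > 0:
            jbar = sum(j * (T[2][j] + T[3][j]) for j in range(nl)) / pool
            ghat = (jbar / m) * csat_pd * (1.0 - B)
            dC -= (Cp / (Cp + gp.K_kill)) * (1.0 - gp.eps_kill * ghat) \
                * sp.kE0 * killers
    dP = -(np.log(2.0) / gp.t_half) * P
    return dT, dD_act, dD_m, dC, dP


def euler_integrate(T0, sp, gp, t_end, dt, D_act=0.0, D_m=0.0, C=0.0, P=0.0,
                    drug_off=True, killing_off=True):
    """Forward-Euler integration of the brute-force system (T grid only)."""
    T = np.array(T0, dtype=float)
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        dT, dDa, dDm, dC, dP = brute_force_rhs(
            T, D_act, D_m, C, P, sp, gp, drug_off, killing_off)
        T = T + dt * dT
        D_act += dt * dDa
        D_m += dt * dDm
        C += dt * dC
        P += dt * dP
    return T, D_act, D_m, C, P


def best_balanced_accuracy(scores, labels):
    """Exhaustive threshold scan scored with scikit-learn (oracle)."""
    from sklearn.metrics import balanced_accuracy_score

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    thresholds = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    return max(balanced_accuracy_score(labels, scores >= t)
               for t in thresholds)
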