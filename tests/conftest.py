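import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def projection_oracle(mu_p: np.ndarray, n_starts: int = 8, seed: int = 0) -> np.ndarray:
    """Independent solver for the E-step projection, row by row.

    For each hidden-unit row a (length n), minimizes ||x - a||^2 over
    {x >= 0, (1/n) sum x^2 = 1} using SLSQP from several random feasible
    starts, keeping the best feasible solution found.  A row with no
    positive entry is left at zero (the documented degenerate convention:
    the normalization is vacuous for an inactive unit).  Deliberately
    knows nothing about the clip-then-rescale shortcut.
    """
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)
    r, n = mu_p.shape
    out = np.zeros_like(mu_p)
    for j in range(r):
        a = mu_p[j]
        if not np.any(a > 0):
            continue
        best_x, best_val = None, np.inf
        starts = [np.abs(rng.normal(size=n)) + 1e-3 for _ in range(n_starts)]
        starts.append(np.maximum(a, 1e-3))
        for x0 in starts:
            x0 = x0 * np.sqrt(n / (x0 @ x0))
            res = minimize(
                lambda x: ((x - a) ** 2).sum(),
                x0,
                method="SLSQP",
                bounds=[(0.0, None)] * n,
                constraints=[{"type": "eq", "fun": lambda x: (x @ x) / n - 1.0}],
                options={"maxiter": 200, "ftol": 1e-12},
            )
            if res.success and abs(res.x @ res.x / n - 1.0) < 1e-6:
                x = np.maximum(res.x, 0.0)
                val = ((x - a) ** 2).sum()
                if val < best_val:
                    best_x, best_val = x, val
        out[j] = best_x
    return out


def classical_fa_em_step(V, W, psi):
    """Textbook factor-analysis EM update, coded from the standard formulas.

    E-step: K = (I + W' Psi^-1 W)^-1, E[h_i] = K W' Psi^-1 V_i,
    E[h h'] = K + E[h] E[h]' (averaged).  M-step: W_new = P Z^-1 with
    P = (1/n) sum V_i E[h_i]', Z = (1/n) sum E[h_i h_i']; Psi_new =
    diag(C - W_new P').
    """
    m, n = V.shape
    r = W.shape[1]
    PsiInv = np.diag(1.0 / psi)
    K = np.linalg.inv(np.eye(r) + W.T @ PsiInv @ W)
    Eh = K @ W.T @ PsiInv @ V  # r x n
    P = V @ Eh.T / n
    Z = Eh @ Eh.T / n + K
    W_new = P @ np.linalg.inv(Z)
    C_diag = np.sum(V * V, axis=1) / n
    psi_new = C_diag - np.sum(W_new * P, axis=1)
    return W_new, np.maximum(psi_new, 1e-4), Eh, K
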