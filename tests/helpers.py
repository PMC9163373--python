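"""Shared oracles for the test suite: brute-force metric recounts, an
independent Newton-Raphson logistic solver, and a direct patient-table
simulator with known logistic truth."""
import numpy as np
import pandas as pd


def dict_labels(P, G):
    ids = [f"n{i}" for i in range(len(P))]
    return (
        {i: list(map(int, row)) for i, row in zip(ids, P)},
        {i: list(map(int, row)) for i, row in zip(ids, G)},
    )


def brute_force_metrics(P, G):
    """Naive loop recount of micro/macro precision/recall/F1 and accuracy."""
    n, k = P.shape
    tp = [0] * k
    fp = [0] * k
    fn = [0] * k
    for i in range(n):
        for j in range(k):
            if P[i, j] == 1 and G[i, j] == 1:
                tp[j] += 1
            elif P[i, j] == 1:
                fp[j] += 1
            elif G[i, j] == 1:
                fn[j] += 1

    def prf(tp_, fp_, fn_):
        p = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
        r = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    micro = prf(sum(tp), sum(fp), sum(fn))
    per = [prf(tp[j], fp[j], fn[j]) for j in range(k)]
    macro = tuple(sum(x[c] for x in per) / k for c in range(3))
    acc = sum(int(P[i, j] == G[i, j]) for i in range(n) for j in range(k)) / (n * k)
    subset = sum(int(all(P[i, j] == G[i, j] for j in range(k))) for i in range(n)) / n
    return micro, macro, acc, subset


def newton_logistic(y, X, iters=200):
    """Independent Newton-Raphson MLE for logistic regression (with intercept)."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    H = np.eye(Xd.shape[1])
    for _ in range(iters):
        p = 1 / (1 + np.exp(-Xd @ beta))
        W = p * (1 - p)
        H = Xd.T @ (Xd * W[:, None])
        g = Xd.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov))


def simulate_patients(n, rng, beta=None, prevalence=None):
    """Patient table with outcome drawn from a known logistic model over the
    five family-history indicators (demographics are null covariates)."""
    beta = np.zeros(5) if beta is None else np.asarray(beta, dtype=float)
    prevalence = np.full(5, 0.1) if prevalence is None else np.asarray(prevalence)
    X = (rng.random((n, 5)) < prevalence).astype(int)
    logits = 1.0 + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    df = pd.DataFrame(X, columns=[f"fh_{c}" for c in ("F20", "F32", "F31", "F28", "F29")])
    df["diagnosis_group"] = np.where(y == 1, "MDD", "BD")
    df["any_family_history"] = (X.sum(axis=1) > 0).astype(int)
    df["age_years"] = rng.integers(18, 80, n)
    df["gender"] = rng.choice(["female", "male"], n)
    df["marital_status"] = rng.choice(["married", "no_spouse"], n, p=[0.7, 0.3])
    df["profession"] = rng.choice(["retiree", "worker", "teacher"], n)
    return df
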