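"""Naive brute-force reference implementations (double loops, no vectorized
shortcuts) used as independent oracles for the stability algorithms."""
import numpy as np
import pandas as pd


def oracle_genorm_m(q: pd.DataFrame) -> pd.Series:
    """Full-panel geNorm M: mean over partners of SD of log2 ratios."""
    genes = list(q.index)
    m = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratios = [np.log2(q.loc[j, s] / q.loc[k, s]) for s in q.columns]
            sds.append(np.std(ratios, ddof=1))
        m[j] = float(np.mean(sds))
    return pd.Series(m)


def oracle_delta_ct(cq: pd.DataFrame) -> pd.Series:
    """Comparative delta-Ct: mean over partners of SD of Cq differences."""
    genes = list(cq.index)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            diffs = [cq.loc[j, s] - cq.loc[k, s] for s in cq.columns]
            sds.append(np.std(diffs, ddof=1))
        out[j] = float(np.mean(sds))
    return pd.Series(out)


def oracle_normfinder_var(y: pd.DataFrame) -> pd.Series:
    """Direct evaluation of the bias-corrected variance-decomposition formula."""
    k, n = y.shape
    arr = y.to_numpy(dtype=float)
    a = []
    for i in range(k):
        total = 0.0
        for j in range(n):
            r = arr[i, j] - arr[i].mean() - arr[:, j].mean() + arr.mean()
            total += r * r
        a.append(total / (n - 1))
    a = np.array(a)
    var = (a - a.sum() / (k * (k - 1))) * k / (k - 2)
    return pd.Series(var, index=y.index)
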