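"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most literal way possible
(explicit loops over risk sets, exhaustive enumeration of label
assignments) and shares no code with the package internals it checks.
"""

from itertools import combinations

import numpy as np


def km_bruteforce(time, event):
    """Product-limit estimate via an explicit loop over risk sets."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(time[event == 1])):
        at_risk = sum(1 for ti in time if ti >= t)
        deaths = sum(1 for ti, ei in zip(time, event) if ti == t and ei == 1)
        s = s * (1 - deaths / at_risk)
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_bruteforce(time_a, event_a, time_b, event_b):
    """Mantel-Cox O/E/V tables accumulated with plain python loops."""
    from scipy.stats import chi2 as chi2_dist

    ta = list(map(float, time_a))
    tb = list(map(float, time_b))
    ea = list(map(int, event_a))
    eb = list(map(int, event_b))
    event_times = sorted(
        set([t for t, e in zip(ta, ea) if e == 1] + [t for t, e in zip(tb, eb) if e == 1])
    )
    O1 = E1 = V = 0.0
    for t in event_times:
        n1 = sum(1 for x in ta if x >= t)
        n2 = sum(1 for x in tb if x >= t)
        d1 = sum(1 for x, e in zip(ta, ea) if x == t and e == 1)
        d2 = sum(1 for x, e in zip(tb, eb) if x == t and e == 1)
        n, d = n1 + n2, d1 + d2
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O1 - E1) ** 2 / V
    return chi2, float(chi2_dist.sf(chi2, 1))


def trimmed_mean_literal(values, trim):
    vals = sorted(values)
    k = int(np.floor(trim * len(vals)))
    kept = vals[k : len(vals) - k]
    return sum(kept) / len(kept)


def exhaustive_permutation_p(lognorm, ligand_row, receptor_row, n_sender, n_receiver,
                             sender_cells, receiver_cells, trim=0.10, Kh=0.5):
    """Exact permutation p over all assignments of cells to the sender and
    receiver label slots (remaining cells take the third label)."""
    n_cells = lognorm.shape[1]
    lig = lognorm[ligand_row]
    rec = lognorm[receptor_row]

    def prob(s_idx, r_idx):
        L = trimmed_mean_literal([lig[i] for i in s_idx], trim)
        R = trimmed_mean_literal([rec[i] for i in r_idx], trim)
        return (L * R) / (Kh + L * R) if L * R > 0 else 0.0

    observed = prob(sender_cells, receiver_cells)
    all_cells = list(range(n_cells))
    count = total = 0
    for s_idx in combinations(all_cells, n_sender):
        rest = [c for c in all_cells if c not in s_idx]
        for r_idx in combinations(rest, n_receiver):
            total += 1
            if prob(s_idx, r_idx) >= observed:
                count += 1
    return observed, count / total


def selection_oracle(records):
    """Straight-line recomputation of candidate selection from a ScreenRecord
    table (pandas DataFrame as written to TSV)."""
    out = {}
    for (ligand, sender), grp in records.groupby(["ligand", "sender"]):
        sum_r = 0.0
        any_pass = False
        for _, row in grp.iterrows():
            if np.isfinite(row["r"]):
                sum_r += row["r"]
            corr_ok = (
                np.isfinite(row["r"])
                and row["r"] < 0
                and np.isfinite(row["r_pvalue"])
                and row["r_pvalue"] < 0.05
            )
            inter_ok = row["interaction_pvalue"] < 0.05
            any_pass = any_pass or (corr_ok and inter_ok)
        out[(ligand, sender)] = any_pass and sum_r < 0
    return out
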