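#!/usr/bin/env python
"""Sequence-dynamics statistics against analytic oracles.

Entropy rate of a known Markov chain, AIF identities, and the DFA Hurst
exponent of sign-thresholded fractional Gaussian noise.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from microdyn.seqstats import aif, dfa_hurst, entropy_rate, joint_entropy
from microdyn.synth import simulate_hurst_sequence, simulate_markov_sequence

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []

    rng = np.random.default_rng(12345)
    p = rng.dirichlet(np.ones(7), size=7)
    seq = simulate_markov_sequence(p, 10**6, seed=42)
    vals, vecs = np.linalg.eig(p.T)
    pi = np.abs(np.real(vecs[:, np.argmax(np.isclose(vals, 1.0))]))
    pi /= pi.sum()
    analytic = float(-(pi[:, None] * p * np.log2(p)).sum())
    est = entropy_rate(seq, k=1)
    rows.append({"statistic": "entropy_rate_markov", "estimate": est, "truth": analytic})
    print(f"Markov chain entropy rate: plug-in {est:.4f} vs analytic {analytic:.4f} bits/sample")

    _, info = aif(seq, max_lag_ms=200)
    rows.append({"statistic": "aif_lag0", "estimate": info[0], "truth": joint_entropy(seq, 1)})
    print(f"AIF identity: I(0) = {info[0]:.4f} = H(X) = {joint_entropy(seq, 1):.4f} bits")

    for h_true in (0.5, 0.7):
        ests = []
        for s in range(10):
            x = 2.0 * simulate_hurst_sequence(h_true, 10**5, seed=s).labels - 1.0
            ests.append(dfa_hurst(x)[0])
        rows.append({"statistic": f"dfa_hurst_h{h_true}", "estimate": float(np.mean(ests)),
                     "truth": h_true})
        print(f"DFA on sign-thresholded fGn (H={h_true}): mean estimate {np.mean(ests):.3f} "
              f"over 10 seeds")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "sequence_oracles.csv", index=False)


if __name__ == "__main__":
    main()
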