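"""Sparse coding and coupled dictionary learning on planted data.

First codes a signal against an orthonormal dictionary, where the exact
solution is entrywise soft-thresholding, then learns a coupled dictionary
pair from signals that are exact 1-sparse combinations of 8 planted atoms
and reports how well the atoms are recovered.
"""

import numpy as np
import rfctsr as rf

rng = np.random.default_rng(0)

# --- orthonormal case: iterative solver vs closed form
Q, _ = np.linalg.qr(rng.normal(size=(16, 16)))
D = rf.Dictionary(Q, normalized=True)
x = rng.normal(size=16)
code = rf.sparse_code(x, D, lam=0.4, max_iter=500)
closed = np.sign(Q.T @ x) * np.maximum(np.abs(Q.T @ x) - 0.2, 0.0)
print(f"solver vs soft-threshold closed form, max |diff|: "
      f"{np.abs(code.alpha - closed).max():.2e}")
print(f"nonzeros kept: {code.nnz} of 16")

# --- planted coupled dictionaries
D_star = rng.normal(size=(12, 8))
D_star /= np.linalg.norm(D_star, axis=0)
codes = np.zeros((8, 400))
idx = rng.integers(8, size=400)
codes[idx, np.arange(400)] = rng.uniform(1, 3, 400) * rng.choice([-1, 1], 400)
X = D_star @ codes

result = rf.learn_coupled_dicts(X, X, B=8, lam=0.01, n_iter=40, seed=1)
corr = np.abs(result.D_H.atoms.T @ D_star)
print(f"objective: {result.objective[0]:.1f} -> {result.objective[-1]:.3f} "
      f"(monotone: {bool(np.all(np.diff(result.objective) <= 1e-8))})")
print(f"worst planted-atom correlation: {corr.max(axis=0).min():.4f}")
print("Correlations near 1 mean every planted atom was recovered up to "
      "sign and permutation.")
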