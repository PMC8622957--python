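"""k-SVD rediscovering a hidden dictionary from sparse signals.

Signals are 3-sparse combinations of a hidden random 20x50 dictionary.
Starting from an unrelated random dictionary, alternating OMP coding and
rank-1 SVD atom updates should rediscover most hidden atoms.
"""

import numpy as np

from scdsparse import CodingConfig, init_dictionary, ksvd_train, make_planted_sparse_set

planted = make_planted_sparse_set(n=20, m=50, M=1000, s=3, noise_sigma=0.0, seed=11)
D0 = init_dictionary(20, 50, seed=99)

learned = ksvd_train(planted.signals, D0, K=20, cfg=CodingConfig(epsilon=1e-6, max_atoms=3))

sims = np.abs(planted.dictionary.atoms.T @ learned.atoms)
recovered = int(np.sum(sims.max(axis=1) > 0.99))
print(f"hidden atoms recovered (|cosine| > 0.99): {recovered}/50")
print(f"total squared coding residual, first iteration: {learned.history[0]:.1f}")
print(f"total squared coding residual, final iteration: {learned.history[-1]:.3f}")
print("-> the residual collapses as the dictionary converges onto the hidden")
print("   atoms; unrecovered atoms are usually rotations within coherent pairs.")
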