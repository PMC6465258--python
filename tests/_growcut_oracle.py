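"""Brute-force reference simulation of the GrowCut update rule.

Independent of the production implementation: plain Python loops over
voxels and neighbors, synchronous updates, strict-improvement conquest
with first-in-lexicographic-order tie-break among equal attackers.
"""

import numpy as np

EPS = 1e-6


def offsets_lex(connectivity):
    if connectivity == 6:
        return [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    return [
        (dz, dr, dc)
        for dz in (-1, 0, 1)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dz, dr, dc) != (0, 0, 0)
    ]


def growcut_bruteforce(I, coords, seed_labels, max_iters=200, connectivity=26,
                       max_intensity_diff=None):
    I = np.asarray(I, dtype=float)
    if max_intensity_diff is None:
        max_intensity_diff = float(I.max() - I.min())
    label = np.zeros(I.shape, dtype=int)
    theta = np.zeros(I.shape, dtype=float)
    for (z, r, c), l in zip(coords, seed_labels):
        label[z, r, c] = l
        theta[z, r, c] = 1.0
    offs = offsets_lex(connectivity)
    S, R, C = I.shape
    iters = 0
    for iters in range(1, max_iters + 1):
        new_label = label.copy()
        new_theta = theta.copy()
        changed = False
        for z in range(S):
            for r in range(R):
                for c in range(C):
                    best_attack = 0.0
                    best_lab = 0
                    for dz, dr, dc in offs:
                        qz, qr, qc = z + dz, r + dr, c + dc
                        if not (0 <= qz < S and 0 <= qr < R and 0 <= qc < C):
                            continue
                        if label[qz, qr, qc] == 0:
                            continue
                        g = 1.0 - abs(I[z, r, c] - I[qz, qr, qc]) / max_intensity_diff
                        g = min(max(g, EPS), 1.0 - EPS)
                        attack = g * theta[qz, qr, qc]
                        if attack > best_attack:
                            best_attack = attack
                            best_lab = label[qz, qr, qc]
                    if best_attack > theta[z, r, c]:
                        if label[z, r, c] != best_lab:
                            changed = True
                        new_label[z, r, c] = best_lab
                        new_theta[z, r, c] = best_attack
        label = new_label
        theta = new_theta
        if not changed:
            break
    return label, iters
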