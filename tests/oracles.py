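"""Independent brute-force reference implementations used by the tests.

These are deliberately written as literal scalar loops over the printed
formulas, sharing no code with the package implementations they check.
"""

import numpy as np


def dice_loss_loop(prob, truth, eps):
    """Global-quotient Dice loss for one sample, scalar loops over classes
    and voxels."""
    n_classes = prob.shape[0]
    num = 0.0
    den = 0.0
    flat_t = truth.ravel()
    flat_p = prob.reshape(n_classes, -1)
    for k in range(n_classes):
        for j in range(flat_t.size):
            ind = 1.0 if flat_t[j] == k else 0.0
            num += ind * flat_p[k, j]
            den += ind * ind + flat_p[k, j] ** 2 + eps
    return -2.0 * num / den


def landmark_loss_loop(prob, lm_labels, clamp=1e-12):
    """Class-balanced weighted cross-entropy, scalar double loop."""
    n_classes = prob.shape[0]
    flat_l = lm_labels.ravel()
    flat_p = prob.reshape(n_classes, -1)
    total_voxels = flat_l.size
    loss = 0.0
    for k in range(n_classes):
        count = int((flat_l == k).sum())
        w = 1.0 - count / total_voxels
        for j in range(total_voxels):
            if flat_l[j] == k:
                loss -= w * np.log(max(flat_p[k, j], clamp))
    return loss


def fuse_labels_loop(target, atlas_vols, atlas_labs, patch_r, window_r, h, n_classes=5):
    """Exhaustive quadruple loop over (voxel, atlas, window offset, class)
    implementing non-local Gaussian-patch-weighted voting.

    Patch distances are means over in-frame patch voxels; window positions
    falling outside the frame cast no vote; ties break to the lower class.
    """
    shape = target.shape
    out = np.zeros(shape, dtype=np.int16)
    pr = patch_r if not np.isscalar(patch_r) else (patch_r,) * 3
    wr = window_r if not np.isscalar(window_r) else (window_r,) * 3

    def patch_dist(x, y, g):
        acc = 0.0
        n = 0
        for dx in range(-pr[0], pr[0] + 1):
            for dy in range(-pr[1], pr[1] + 1):
                for dz in range(-pr[2], pr[2] + 1):
                    xi = (x[0] + dx, x[1] + dy, x[2] + dz)
                    yi = (y[0] + dx, y[1] + dy, y[2] + dz)
                    if any(c < 0 or c >= s for c, s in zip(xi, shape)):
                        continue
                    if any(c < 0 or c >= s for c, s in zip(yi, shape)):
                        continue
                    acc += (target[xi] - g[yi]) ** 2
                    n += 1
        return acc / max(n, 1)

    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                votes = np.zeros(n_classes)
                for g, lab in zip(atlas_vols, atlas_labs):
                    for ox in range(-wr[0], wr[0] + 1):
                        for oy in range(-wr[1], wr[1] + 1):
                            for oz in range(-wr[2], wr[2] + 1):
                                y = (i + ox, j + oy, k + oz)
                                if any(c < 0 or c >= s for c, s in zip(y, shape)):
                                    continue
                                w = np.exp(-patch_dist((i, j, k), y, g) / h)
                                votes[lab[y]] += w
                out[i, j, k] = int(np.argmax(votes))
    return out
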