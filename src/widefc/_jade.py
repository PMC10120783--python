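"""Joint Approximate Diagonalization of Eigenmatrices (JADE) ICA.

Fourth-order-cumulant ICA: the data are whitened by PCA, the full set of
parallel fourth-order cumulant matrices is estimated, and an orthogonal
rotation jointly diagonalizing them is found by Jacobi sweeps.  Used for
spatial unmixing of SVD-compressed widefield movies.
"""

from __future__ import annotations

import numpy as np


def jade(X: np.ndarray, n_components: int | None = None, max_sweeps: int = 100,
         tol: float | None = None) -> np.ndarray:
    """Estimate an unmixing matrix B with sources S = B @ X.

    Parameters
    ----------
    X : (n_signals, n_samples) zero-mean data matrix.
    n_components : number of sources to extract (default: n_signals).
    max_sweeps : cap on Jacobi sweeps over all rotation pairs.
    tol : rotation-angle threshold for convergence (default 1/sqrt(n_samples)/100).

    Raises RuntimeError when the Jacobi sweeps do not converge.
    """
    X = np.asarray(X, float)
    n, T = X.shape
    m = n_components or n
    if m > n:
        raise ValueError("n_components cannot exceed n_signals")
    X = X - X.mean(axis=1, keepdims=True)

    # --- whitening by PCA ---
    R = (X @ X.T) / T
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1][:m]
    lam = np.clip(eigval[order], 1e-12, None)
    W = (eigvec[:, order] / np.sqrt(lam)).T  # (m, n)
    Y = W @ X  # whitened, (m, T)

    # --- cumulant matrices (parallel set, whitened convention) ---
    nbcm = m * (m + 1) // 2
    CM = np.empty((m, m * nbcm))
    I = np.eye(m)
    k = 0
    for p in range(m):
        for q in range(p + 1):
            w = Y[p] * Y[q]
            Q = (Y * w) @ Y.T / T
            if p == q:
                Q -= I + 2 * np.outer(I[p], I[p])
            else:
                Q -= np.outer(I[p], I[q]) + np.outer(I[q], I[p])
                Q *= np.sqrt(2.0)  # weight so the set approximates the full cumulant tensor
            CM[:, k * m:(k + 1) * m] = Q
            k += 1

    # --- joint diagonalization by Jacobi rotations ---
    V = np.eye(m)
    threshold = tol if tol is not None else 1.0 / np.sqrt(T) / 100.0
    converged = False
    for _ in range(max_sweeps):
        rotated = False
        for p in range(m - 1):
            for q in range(p + 1, m):
                Ip = np.arange(p, m * nbcm, m)
                Iq = np.arange(q, m * nbcm, m)
                g = np.vstack([CM[p, Ip] - CM[q, Iq], CM[p, Iq] + CM[q, Ip]])
                G = g @ g.T
                ton = G[0, 0] - G[1, 1]
                toff = G[0, 1] + G[1, 0]
                theta = 0.5 * np.arctan2(toff, ton + np.sqrt(ton * ton + toff * toff))
                if abs(theta) > threshold:
                    rotated = True
                    c, s = np.cos(theta), np.sin(theta)
                    pair = np.array([[c, -s], [s, c]])
                    V[:, [p, q]] = V[:, [p, q]] @ pair
                    CM[[p, q], :] = pair.T @ CM[[p, q], :]
                    cp, cq = CM[:, Ip].copy(), CM[:, Iq].copy()
                    CM[:, Ip] = c * cp + s * cq
                    CM[:, Iq] = -s * cp + c * cq
        if not rotated:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"JADE joint diagonalization did not converge within {max_sweeps} sweeps "
            f"(threshold {threshold:.2e})")
    return V.T @ W
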