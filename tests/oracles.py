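"""Independent oracles used by the test suite.

These re-derive expected values through a different route than the
package (explicit recursion on the dendropy tree, vectorized over a dense
rate grid) so agreement is meaningful.
"""

import numpy as np

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def dense_grid_loglik(tree, column, lams):
    """Log-likelihood of one column at every rate in ``lams``.

    Direct recursive Felsenstein pruning under Jukes-Cantor, vectorized
    over the rate grid; written independently of the package's iterative
    implementation.
    """
    lams = np.asarray(lams, dtype=float)

    def partial(node):
        if node.is_leaf():
            base = column.get(node.taxon.label)
            vec = np.ones((lams.size, 4))
            if base in _IDX:
                vec[:] = 0.0
                vec[:, _IDX[base]] = 1.0
            return vec
        out = np.ones((lams.size, 4))
        for child in node.child_nodes():
            t = (child.edge.length or 0.0) * lams
            e = np.exp(-4.0 * t / 3.0)[:, None]
            L = partial(child)
            out *= 0.25 * (1 - e) * L.sum(axis=1, keepdims=True) + e * L
        return out

    lk = 0.25 * partial(tree.seed_node).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(lk)


def dense_grid_argmax(tree, column, cap=20.0, step=1e-3):
    """Rate-grid argmax of the column log-likelihood (grid step 1e-3)."""
    grid = np.arange(step, cap + step / 2, step)
    ll = dense_grid_loglik(tree, column, grid)
    return float(grid[int(np.argmax(ll))])
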