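"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's own linear-algebra shortcuts:
the GLS oracle goes through explicit dense inverses and scipy's
multivariate-normal density; the covariance oracle derives MRCA depths
from dendropy's patristic distances and root distances.
"""

import dendropy
import numpy as np
from scipy import stats


def dense_gls(X, y, V):
    """GLS via explicit dense inversion; loglik via scipy's MVN density.

    Returns (beta, se, sigma2, loglik) with ML sigma2 and OLS-style
    small-sample SE correction n/(n-p).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    V = np.asarray(V, float)
    n, p = X.shape
    Vi = np.linalg.inv(V)
    M = X.T @ Vi @ X
    Minv = np.linalg.inv(M)
    beta = Minv @ X.T @ Vi @ y
    r = y - X @ beta
    sigma2 = float(r @ Vi @ r) / n
    loglik = float(
        stats.multivariate_normal(mean=X @ beta, cov=sigma2 * V, allow_singular=True).logpdf(y)
    )
    se = np.sqrt(np.diag(Minv) * sigma2 * n / (n - p))
    return beta, se, sigma2, loglik


def brute_vcv(newick: str, taxa):
    """MRCA-depth matrix from dendropy's own distance calculations.

    V[i, j] = (depth_i + depth_j - patristic(i, j)) / 2; diagonal from
    root distances.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.calc_node_root_distances()
    depth = {
        leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()
    }
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    V = np.zeros((n, n))
    for i, a in enumerate(taxa):
        V[i, i] = depth[a]
        for j in range(i + 1, n):
            b = taxa[j]
            d = pdm.patristic_distance(tax[a], tax[b])
            V[i, j] = V[j, i] = (depth[a] + depth[b] - d) / 2.0
    return V
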