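"""Shared test utilities: random fixtures and naive oracles."""

import numpy as np

from gdaa import CorrelationSample, fisher_transform, pearson_correlation


def random_corr_sample(rng, m, G, scale=1.0):
    """A valid CorrelationSample: G symmetric m×m matrices with zero diagonal."""
    mats = []
    for _ in range(G):
        w = rng.normal(scale=scale, size=(m, m))
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        mats.append(w)
    return CorrelationSample(mats)


def naive_correlation_matrices(values, part):
    """Per-pair loop over pearson_correlation + fisher_transform."""
    m = values.shape[0]
    mats = []
    for idx in part.subgroups:
        block = values[:, idx]
        w = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                if i != j:
                    w[i, j] = fisher_transform(pearson_correlation(block[i], block[j]))
        mats.append(w)
    return mats
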