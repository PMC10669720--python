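import numpy as np
import pytest

from pcgcaps.preprocess import preprocess_recording
from pcgcaps.synthetic import SynthConfig, generate_dataset
from pcgcaps.train_eval import SpectrumDataset


@pytest.fixture(scope="session")
def small_synth_dataset():
    """120 synthetic recordings (60/class) preprocessed to spectra,
    split 100 train / 20 validation."""
    recs = generate_dataset(60, SynthConfig(seed=7))
    spectra = [preprocess_recording(r)[0] for r in recs]
    ds = SpectrumDataset.from_spectra(spectra)
    order = np.random.default_rng(7).permutation(len(ds))
    tr, va = order[:100], order[100:]
    train = SpectrumDataset(ds.X[tr], ds.y[tr], [ds.ids[i] for i in tr])
    val = SpectrumDataset(ds.X[va], ds.y[va], [ds.ids[i] for i in va])
    return train, val


def naive_squash(v):
    """Literal squash: (|v|^2/(1+|v|^2)) * v/|v|."""
    n2 = float(np.dot(v, v))
    if n2 == 0.0:
        return np.zeros_like(v)
    return (n2 / (1.0 + n2)) * v / np.sqrt(n2)


def naive_routing(primary, W, routings, record=None):
    """Unvectorized routing-by-agreement reference.

    Follows the update equations line by line with explicit loops:
    predictions u_{j|i} = W_ij s_i, couplings c_ij = softmax_j(b_ij),
    s_j = sum_i c_ij u_{j|i}, v_j = squash(s_j), then
    b_ij += u_{j|i} . v_j.  Independent of the vectorized path.
    """
    M, J = W.shape[0], W.shape[1]
    D = W.shape[2]
    u = np.empty((M, J, D))
    for i in range(M):
        s_i = naive_squash(primary[i])
        for j in range(J):
            u[i, j] = W[i, j] @ s_i
    b = np.zeros((M, J))
    v = np.zeros((J, D))
    for r in range(routings):
        c = np.empty((M, J))
        for i in range(M):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        if record is not None:
            record.append(c.copy())
        for j in range(J):
            s = np.zeros(D)
            for i in range(M):
                s += c[i, j] * u[i, j]
            v[j] = naive_squash(s)
        if r < routings - 1:
            for i in range(M):
                for j in range(J):
                    b[i, j] += u[i, j] @ v[j]
    return v
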