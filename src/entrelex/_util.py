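"""Small internal helpers."""

from __future__ import annotations

import warnings
from contextlib import contextmanager

import numpy as np
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning


@contextmanager
def quiet_convergence():
    """Suppress liblinear convergence warnings during hyperparameter
    search; the finally-selected model is refitted normally."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


def csr32(x: sp.spmatrix) -> sp.csr_matrix:
    """CSR matrix with 32-bit indices (required by liblinear/libsvm)."""
    x = x.tocsr()
    x.indices = x.indices.astype(np.int32, copy=False)
    x.indptr = x.indptr.astype(np.int32, copy=False)
    return x
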