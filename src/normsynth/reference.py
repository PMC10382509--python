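"""Published benchmark eigenvalue spectra used in worked examples.

These are the eigenvalues of the normalized-variable (Y) covariance matrices
reported for three n=667, d=10 benchmark samples: two mammography feature
sets (Fourier power-spectrum measures; image summary measures) and a random
dry-bean morphology subset.  Because each Y variable has unit variance, the
spectra sum to d = 10 and a single eigenvalue times 10 is the percentage of
total variance its component explains.
"""

from __future__ import annotations

import numpy as np

BENCHMARK_EIGENVALUES: dict[str, np.ndarray] = {
    "mammography_fourier": np.array(
        [7.6178, 1.0682, 0.9634, 0.2208, 0.0544,
         0.0244, 0.0166, 0.0142, 0.0116, 0.0085]
    ),
    "mammography_summary": np.array(
        [4.8873, 2.3806, 1.1083, 0.6618, 0.3575,
         0.2579, 0.1576, 0.1064, 0.0590, 0.0235]
    ),
    "dry_bean": np.array(
        [4.1932, 2.6215, 1.4759, 0.9790, 0.4877,
         0.2286, 0.0116, 0.0015, 0.0009, 0.0001]
    ),
}

#: sample size shared by the three benchmark samples
BENCHMARK_N = 667
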