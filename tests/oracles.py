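"""Independent numerical oracles shared by the test suite."""
import numpy as np
from scipy.integrate import quad
from scipy.stats import norm


def bhattacharyya_quadrature(mu1, s1, mu2, s2):
    """Independent oracle: -ln integral sqrt(p q) by numerical quadrature.

    sqrt(p q) is a Gaussian-shaped bump; integrating over its own support
    with a relative tolerance keeps the oracle accurate even when the
    coefficient is astronomically small.
    """
    a = 1.0 / (4 * s1**2) + 1.0 / (4 * s2**2)
    center = (mu1 / (4 * s1**2) + mu2 / (4 * s2**2)) / a
    width = np.sqrt(1.0 / (2 * a))

    def log_integrand(x):
        return 0.5 * (norm.logpdf(x, mu1, s1) + norm.logpdf(x, mu2, s2))

    peak = log_integrand(center)  # factor the peak out to dodge underflow
    scaled, _ = quad(
        lambda x: np.exp(log_integrand(x) - peak),
        center - 15 * width, center + 15 * width,
        epsabs=0.0, epsrel=1e-11, limit=300,
    )
    return -(peak + np.log(scaled))
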