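import numpy as np
import pytest

from nefr import NEFrParams, load_fixture

# parameter panel spanning lam < 1, lam = 1, lam > 1 (and the lam = 2
# boundary where the series representation stops converging classically)
PARAM_PANEL = [
    NEFrParams(0.5, 1.0, 2.0),
    NEFrParams(0.4, 0.4, 0.9),
    NEFrParams(0.5, 3.0, 1.0),
    NEFrParams(0.5, 3.0, 0.8),
    NEFrParams(2.0, 1.5, 1.7),
]


@pytest.fixture(scope="session")
def bladder():
    return load_fixture("bladder_cancer")


@pytest.fixture(scope="session")
def pakistan():
    return load_fixture("pakistan_covid_cases")


@pytest.fixture(scope="session")
def who():
    return load_fixture("who_covid_deaths")


@pytest.fixture(scope="session")
def mp_oracle():
    """Arbitrary-precision evaluation of the distribution's defining formulas,
    independent of the package's log-scale implementation."""
    import mpmath

    mpmath.mp.dps = 40

    class Oracle:
        @staticmethod
        def cdf(z, a, b, l):
            z, a, b, l = map(mpmath.mpf, (z, a, b, l))
            E = mpmath.e ** (-2 * a * z**-b)
            return float(1 - ((1 - E) / (1 - (1 - l) * E)) ** l)

        @staticmethod
        def pdf(z, a, b, l):
            z, a, b, l = map(mpmath.mpf, (z, a, b, l))
            E = mpmath.e ** (-2 * a * z**-b)
            return float(
                2 * l**2 * a * b * z ** (-b - 1) * E
                * (1 - E) ** (l - 1) / (1 - (1 - l) * E) ** (l + 1)
            )

        @staticmethod
        def logpdf(z, a, b, l):
            import mpmath as mp

            z, a, b, l = map(mp.mpf, (z, a, b, l))
            w = 2 * a * z**-b
            E = mp.e**-w
            return float(
                mp.log(2 * l**2 * a * b) - (b + 1) * mp.log(z) - w
                + (l - 1) * mp.log(1 - E) - (l + 1) * mp.log(1 - (1 - l) * E)
            )

    return Oracle()


def mc_se(sq_errors: np.ndarray) -> float:
    """Monte-Carlo standard error of an MSE estimate."""
    return float(sq_errors.std(ddof=1) / np.sqrt(sq_errors.size))
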