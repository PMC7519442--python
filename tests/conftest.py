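import pytest

from tissuepk.calibration import CalibrationCurve
from tissuepk.datamodel import ConcentrationProfile, TimePointStats, load_design


@pytest.fixture(scope="session")
def design():
    return load_design()


@pytest.fixture
def kidney_curve():
    """Weighted-linear curve over 2-1000 ng/mL with a realistic slope/intercept."""
    return CalibrationCurve(compound="psoralen", tissue="kidney",
                            slope=3.44e-3, intercept=1.21e-1, r=0.9996,
                            range_low=2.0, range_high=1000.0, lloq=2.0)


def make_profile(points, compound="c", tissue="kidney", group="crude"):
    """Build a profile from (time, values) or (time, mean, sd, n) tuples."""
    stats = []
    for entry in points:
        if len(entry) == 2:
            t, values = entry
            values = tuple(float(v) for v in values)
            n = len(values)
            mean = sum(values) / n
            sd = (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5 if n > 1 else 0.0
            stats.append(TimePointStats(time_min=t, values=values, mean=mean,
                                        sd=sd, n=n))
        else:
            t, mean, sd, n = entry
            stats.append(TimePointStats(time_min=t, values=(), mean=mean,
                                        sd=sd, n=n))
    return ConcentrationProfile(compound=compound, tissue=tissue, group=group,
                                points=tuple(stats))
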