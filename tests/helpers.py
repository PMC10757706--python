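"""Shared test toys."""

import numpy as np

from smorepars.calibration import SurrogateCalibration
from smorepars.data import Arm, TimeSeriesDataset


class LinearCalibration(SurrogateCalibration):
    """y = theta * x with Gaussian noise; 'lam' plays the role of theta.

    Only ``predict`` is overridden, so the optimization and profiling
    machinery runs unchanged on a problem with a closed-form Wald interval.
    With ``product=True`` the slope is ``lam * alpha`` - a constructed
    non-identifiable model whose profiles are flat along the product.
    """

    def __init__(self, x, y, sigma, product=False):
        arm = Arm(dose=0.0, observable="total_count", times=x, mean=y,
                  sd=np.full_like(np.asarray(x, float), sigma))
        super().__init__(TimeSeriesDataset(arms=(arm,), provenance="synthetic"),
                         model="control", fit_initial_split=False)
        self._x = np.asarray(x, float)
        self._product = product

    def predict(self, theta):
        th = self._as_dict(theta)
        slope = th["lam"] * th["alpha"] if self._product else th["lam"]
        return {(0.0, "total_count"): slope * self._x}
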