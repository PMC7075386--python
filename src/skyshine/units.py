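"""Centralized unit conversions for dose bookkeeping.

Photons carry a radiation weighting factor of 1, so absorbed dose and
dose equivalent are numerically interchangeable here:
1 cGy <-> 1 rem <-> 1000 mrem <-> 10 mSv.
"""

MREM_PER_CGY = 1000.0  # photon weighting factor 1: 1 cGy = 1 rem = 1000 mrem
NSV_PER_S_TO_USV_PER_H = 3.6
SECONDS_PER_MINUTE = 60.0
CGY_PER_GY = 100.0


def cgy_to_mrem(dose_cgy: float) -> float:
    return dose_cgy * MREM_PER_CGY


def cgy_per_min_to_gy_per_h(rate_cgy_min: float) -> float:
    return rate_cgy_min * 0.6


def nsv_per_s_to_usv_per_h(rate_nsv_s: float) -> float:
    return rate_nsv_s * NSV_PER_S_TO_USV_PER_H
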