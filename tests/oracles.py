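"""Independent brute-force oracles, written as plain Python loops.

These deliberately avoid the vectorised code paths (and, where cheap,
numpy itself) so that agreement with the package is a genuine two-route
check rather than the same arithmetic twice.
"""

import math


def mcnamara_scalar(d, let, alpha_beta, c1=0.99064, c2=0.35605, c3=1.1012,
                    c4=0.0038703):
    rmax = c1 + c2 * let / alpha_beta
    rmin = max(c3 - c4 * math.sqrt(alpha_beta) * let, 0.0)
    disc = alpha_beta ** 2 + 4 * d * alpha_beta * rmax + 4 * d * d * rmin * rmin
    return (math.sqrt(disc) - alpha_beta) / (2 * d)


def _finite(values):
    return [v for v in values if math.isfinite(v)]


def mean_oracle(values):
    vals = _finite(values)
    return sum(vals) / len(vals)


def d_volume_oracle(values, voxel_cc, volume_cc):
    """Sort-descending / accumulate / linear-interpolate, loop style."""
    ordered = sorted(_finite(values), reverse=True)
    cum = 0.0
    prev_cum, prev_val = None, None
    for v in ordered:
        cum += voxel_cc
        if cum >= volume_cc:
            if prev_cum is None or cum == volume_cc:
                return v if prev_cum is None else (
                    prev_val + (v - prev_val) * (volume_cc - prev_cum) / (cum - prev_cum))
            return prev_val + (v - prev_val) * (volume_cc - prev_cum) / (cum - prev_cum)
        prev_cum, prev_val = cum, v
    raise ValueError("structure smaller than requested volume")


def dvh_volume_oracle(values, edge):
    """% of evaluable voxels with value >= edge."""
    vals = _finite(values)
    return 100.0 * sum(1 for v in vals if v >= edge) / len(vals)


def v_dose_oracle(values, threshold):
    """% of all voxels (sentinels count as below) with value >= threshold."""
    hit = sum(1 for v in values if math.isfinite(v) and v >= threshold)
    return 100.0 * hit / len(values)


def volume_above_oracle(values, voxel_cc, threshold):
    return voxel_cc * sum(1 for v in values if math.isfinite(v) and v >= threshold)


def overlap_oracle(dose_values, let_values, voxel_cc, dose_cut, let_cut):
    n = 0
    for d, l in zip(dose_values, let_values):
        if d >= dose_cut and math.isfinite(l) and l >= let_cut:
            n += 1
    return n * voxel_cc


def mix_voxel_oracle(doses, lets):
    den = sum(doses)
    if den == 0:
        return None
    return sum(d * l for d, l in zip(doses, lets) if d > 0) / den


def threshold_survivor_count(dose_values, let_values, fraction):
    dmax = max(dose_values)
    cut = fraction * dmax
    return sum(1 for d, l in zip(dose_values, let_values)
               if d >= cut and math.isfinite(l))


def percentile_exceeded_by(values, frac):
    """Value exceeded (>=) by a fraction ``frac`` of voxels: sort + index."""
    ordered = sorted(values, reverse=True)
    k = math.ceil(frac * len(ordered))
    return ordered[k - 1]
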