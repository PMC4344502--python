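"""Bead-array profiling normalization and total-miRNA abundance.

Two normalization modes, mirroring the two assumptions used for
transcription-shutoff profiling data:

* spike-in: each sample is rescaled so the geometric mean of its
  spike-in probe intensities matches the across-sample reference,
  putting intensities on a per-total-RNA scale;
* total-constant: each sample is rescaled so the sum over mature probes
  is the same in every sample, assuming total miRNA content is constant.

Both are pure per-sample rescalings and therefore preserve within-sample
probe ratios exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ProfilingError(ValueError):
    pass


@dataclass
class ProfilingMatrix:
    """Probe x sample intensity matrix with probe classes and sample metadata."""

    values: pd.DataFrame       # probes x samples, intensities >= 0
    probe_class: pd.Series     # "mature" | "spikein" | "control"
    samples: pd.DataFrame | None = None   # optional: time_h, replicate per sample

    def __post_init__(self):
        self.probe_class = self.probe_class.reindex(self.values.index)
        if self.probe_class.isna().any():
            missing = list(self.probe_class[self.probe_class.isna()].index)
            raise ProfilingError(f"probes without a class: {missing[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ProfilingError("negative intensities")

    def rows(self, cls: str) -> pd.DataFrame:
        return self.values.loc[self.probe_class == cls]

    def scaled(self, factors: pd.Series) -> "ProfilingMatrix":
        return ProfilingMatrix(self.values * factors, self.probe_class,
                               self.samples)


def spikein_normalize(m: ProfilingMatrix) -> ProfilingMatrix:
    """Rescale each sample by its spike-in level.

    scale_s = (geometric mean of spike-in geomeans across samples)
              / (geometric mean of the sample's spike-in intensities).
    Spike-in rows are near-equal across samples afterwards.
    """
    spikes = m.rows("spikein")
    if len(spikes) == 0:
        raise ProfilingError("no spike-in probes")
    bad = (spikes <= 0)
    if bad.to_numpy().any():
        probe = bad.any(axis=1).idxmax()
        sample = bad.loc[probe].idxmax()
        raise ProfilingError(
            f"non-positive spike-in intensity: probe {probe!r}, sample {sample!r}")
    per_sample = np.exp(np.log(spikes).mean(axis=0))     # geomean per sample
    reference = stats.gmean(per_sample)
    factors = reference / per_sample
    return m.scaled(factors)


def total_constant_normalize(m: ProfilingMatrix) -> ProfilingMatrix:
    """Rescale each sample so its mature-probe sum equals the across-sample mean."""
    mature = m.rows("mature")
    if len(mature) == 0:
        raise ProfilingError("no mature probes")
    sums = mature.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ProfilingError(
            f"all-zero mature probes in sample {zero.index[0]!r}")
    factors = sums.mean() / sums
    return m.scaled(factors)


def total_mirna_abundance(m: ProfilingMatrix) -> pd.DataFrame:
    """Per-sample total mature intensity, with the time trend when known.

    Run this on spike-in-normalized data so totals reflect miRNA amount
    per total RNA. Returns one row per sample (total, time_h) plus
    per-timepoint means; the fitted slope of total vs time and its 95%
    confidence interval are attached as DataFrame attrs.
    """
    totals = m.rows("mature").sum(axis=0).rename("total")
    out = totals.to_frame()
    if m.samples is not None:
        sheet = m.samples.set_index("sample_id") \
            if "sample_id" in m.samples.columns else m.samples
        out["time_h"] = sheet.loc[out.index, "time_h"].to_numpy()
        out["timepoint_mean"] = out.groupby("time_h")["total"].transform("mean")
        if out["time_h"].nunique() >= 2:
            fit = stats.linregress(out["time_h"], out["total"])
            # 95% CI on the slope
            tcrit = stats.t.ppf(0.975, len(out) - 2)
            out.attrs["slope"] = fit.slope
            out.attrs["slope_ci"] = (fit.slope - tcrit * fit.stderr,
                                     fit.slope + tcrit * fit.stderr)
    return out


def load_profiling(matrix_tsv, probes_tsv, samples_tsv=None) -> ProfilingMatrix:
    """Read a probes x samples TSV plus a probe-class TSV (probe_id, probe_class)."""
    values = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    probes = pd.read_csv(probes_tsv, sep="\t", index_col=0)
    samples = pd.read_csv(samples_tsv, sep="\t") if samples_tsv else None
    return ProfilingMatrix(values, probes["probe_class"], samples)
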