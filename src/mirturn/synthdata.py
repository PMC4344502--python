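"""Synthetic small-RNA turnover data with known ground truth.

The generator emulates a transcription-shutoff (actinomycin D) time
course read out by small-RNA sequencing: a miRBase-style hairpin
reference with annotated 5p/3p mature arms, a minority of fast-turnover
species (biased toward star strands) decaying as a two-pool mixture
(fast pool half-life ~1 h plus a residual stable pool), ultrafast
loop-region byproducts, an isoform spectrum dominated by one sequence
(~90%), three constant spike-ins, and negative-binomial count noise.
A companion routine simulates a bead-array profiling matrix with
per-sample scale factors and spike-in probe rows.

Everything is driven by a single :class:`~mirturn.config.SimConfig` and a
seed; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import NTS, SimConfig
from .reference import HairpinRecord, MatureAnnotation, Reference, write_fasta, write_reference

MATURE_LEN = 22
A_WINDOW = (13, 16)          # 1-based inclusive positions carrying the A-rich bias

# minor-isoform spectrum: (5' offset, 3' offset) relative to the annotated
# mature; positive off5 trims the 5' end, negative off3 trims the 3' end,
# the remaining two are one-base templated extensions.
_MINOR_OFFSETS = [(1, 0), (2, 0), (0, -1), (0, -2), (-1, 0), (0, 1)]
_MINOR_DECAY = 0.5           # geometric weight per trimmed/extended base


@dataclass
class SimulatedTimecourse:
    """Read counts per unique sequence per sample, with full provenance."""

    counts: pd.DataFrame       # index: sequence; columns: sample ids (ints)
    expected: pd.DataFrame     # per-emitted-isoform metadata + expected counts
    samples: pd.DataFrame      # sample_id, time_h, replicate
    reference: Reference
    spikeins: dict


@dataclass
class SimulatedProfiling:
    """Bead-array-style intensity matrix with known scale factors."""

    matrix: pd.DataFrame       # probes x samples, scaled + noisy
    probe_class: pd.Series     # "mature" | "spikein" | "control"
    samples: pd.DataFrame
    scale_factors: pd.Series
    expected: pd.DataFrame     # unscaled, noiseless intensities


def _draw_base(rng, dist: dict) -> str:
    return rng.choice(NTS, p=[dist[n] for n in NTS])


def _mature_sequence(rng, fast: bool, bias) -> str:
    first = bias.first_base_fast if fast else bias.first_base_slow
    last = bias.last_base_fast if fast else bias.last_base_slow
    p_a = bias.a_window_fast if fast else bias.a_window_slow
    seq = []
    for pos1 in range(1, MATURE_LEN + 1):
        if pos1 == 1:
            seq.append(_draw_base(rng, first))
        elif pos1 == MATURE_LEN:
            seq.append(_draw_base(rng, last))
        elif A_WINDOW[0] <= pos1 <= A_WINDOW[1]:
            if rng.random() < p_a:
                seq.append("A")
            else:
                seq.append(rng.choice(["C", "G", "T"]))
        else:
            seq.append(rng.choice(NTS))
    return "".join(seq)


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(NTS, size=length))


def generate_reference(config: SimConfig):
    """Build hairpins, mature annotations, spike-ins and the truth table.

    Returns ``(reference, spikeins, truth)`` where ``truth`` has one row
    per mature species with its planted kinetic class, two-pool
    parameters, strand role and relative abundance. Each hairpin carries
    a 5p and a 3p 22-nt mature arm separated by a >=15-nt loop; mature
    sequences are unique across the reference and the three spike-ins
    occur in no hairpin.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_species = 2 * config.n_hairpins

    # strand roles and abundances (non-star:star skewed >= star_ratio_min)
    star_arm = rng.choice(["5p", "3p"], size=max(config.n_hairpins, 1))
    nonstar_abund = rng.lognormal(0.0, config.abundance_sigma, size=max(config.n_hairpins, 1))
    star_ratio = config.star_ratio_min * np.exp(np.abs(rng.normal(0.0, 0.5,
                                                                  size=max(config.n_hairpins, 1))))

    species = []   # (hairpin index, arm)
    roles = {}
    abund = {}
    for i in range(config.n_hairpins):
        for arm in ("5p", "3p"):
            species.append((i, arm))
            if arm == star_arm[i]:
                roles[(i, arm)] = "star"
                abund[(i, arm)] = nonstar_abund[i] / star_ratio[i]
            else:
                roles[(i, arm)] = "non_star"
                abund[(i, arm)] = nonstar_abund[i]

    # fast-class assignment, biased toward star strands
    n_fast = int(round(config.frac_fast * n_species))
    stars = [s for s in species if roles[s] == "star"]
    nonstars = [s for s in species if roles[s] == "non_star"]
    rng.shuffle(stars)
    rng.shuffle(nonstars)
    fast_set = set()
    for _ in range(n_fast):
        want_star = rng.random() < config.frac_fast_star_bias
        pool = stars if (want_star and stars) or not nonstars else nonstars
        fast_set.add(pool.pop())

    lo, hi = config.stable_fraction_range
    seen = set()
    hairpins = []
    truth_rows = []
    for i in range(config.n_hairpins):
        arm_seqs = {}
        for arm in ("5p", "3p"):
            fast = (i, arm) in fast_set
            for _ in range(1000):
                s = _mature_sequence(rng, fast, config.seq_bias)
                if s not in seen:
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a unique mature sequence")
            seen.add(s)
            arm_seqs[arm] = s
        flank5 = _random_seq(rng, int(rng.integers(4, 9)))
        loop = _random_seq(rng, int(rng.integers(15, 19)))
        flank3 = _random_seq(rng, int(rng.integers(4, 9)))
        hp_seq = flank5 + arm_seqs["5p"] + loop + arm_seqs["3p"] + flank3
        hid = f"hp-{i:05d}"
        s5 = len(flank5)
        s3 = len(flank5) + MATURE_LEN + len(loop)
        hp = HairpinRecord(hairpin_id=hid, sequence=hp_seq, mature={
            "5p": MatureAnnotation(f"mir-{i:05d}-5p", "5p", s5, s5 + MATURE_LEN),
            "3p": MatureAnnotation(f"mir-{i:05d}-3p", "3p", s3, s3 + MATURE_LEN),
        })
        hairpins.append(hp)
        for arm in ("5p", "3p"):
            fast = (i, arm) in fast_set
            f_slow = float(rng.uniform(lo, hi)) if fast else math.nan
            truth_rows.append({
                "mature_id": hp.mature[arm].mature_id,
                "hairpin_id": hid, "arm": arm,
                "sequence": arm_seqs[arm],
                "strand_role": roles[(i, arm)],
                "true_class": "fast" if fast else "slow",
                "abundance": abund[(i, arm)],
                "f_slow": f_slow,
                "h_fast": config.h_fast if fast else math.nan,
                "h_slow": config.h_slow,
            })

    spikeins = {}
    hairpin_blob = "\n".join(hp.sequence for hp in hairpins)
    k = 0
    while len(spikeins) < 3:
        s = _random_seq(rng, MATURE_LEN)
        if s not in hairpin_blob and s not in seen:
            spikeins[f"spike-{k + 1}"] = s
            seen.add(s)
            k += 1

    truth = pd.DataFrame(truth_rows, columns=[
        "mature_id", "hairpin_id", "arm", "sequence", "strand_role",
        "true_class", "abundance", "f_slow", "h_fast", "h_slow"])
    return Reference(hairpins), spikeins, truth


def species_remaining(row, t: float) -> float:
    """Planted decay law: fraction of a species remaining at time t (hours)."""
    if row["true_class"] == "fast":
        fs = row["f_slow"]
        return fs * 2.0 ** (-t / row["h_slow"]) + (1.0 - fs) * 2.0 ** (-t / row["h_fast"])
    return 2.0 ** (-t / row["h_slow"])


def _isoform_spectrum(config: SimConfig):
    """(off5, off3, fraction) triples; the dominant isoform first."""
    minor_total = 1.0 - config.dominant_isoform_frac
    weights = [_MINOR_DECAY ** (abs(a) + abs(b)) for a, b in _MINOR_OFFSETS]
    wsum = sum(weights)
    out = [(0, 0, config.dominant_isoform_frac)]
    for (a, b), w in zip(_MINOR_OFFSETS, weights):
        out.append((a, b, minor_total * w / wsum))
    return out


def simulate_timecourse_reads(reference: Reference, truth: pd.DataFrame,
                              config: SimConfig) -> SimulatedTimecourse:
    """Draw per-sample read counts around the planted decay expectations.

    Expected counts are scaled so the 0-h samples carry ``config.depth``
    mature-mapped reads in expectation; later samples shrink in
    proportion to the total surviving miRNA content (a small effect at
    default settings, since most species are stable). Counts are
    negative-binomial with dispersion ``nb_dispersion`` (Poisson at 0).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    spectrum = _isoform_spectrum(config)
    truth = truth.set_index("mature_id", drop=False)

    rows = []
    for hp in reference:
        loop = hp.loop
        hp_abund0 = 0.0
        for arm, ann in hp.mature.items():
            trow = truth.loc[ann.mature_id]
            hp_abund0 += trow["abundance"]
            for off5, off3, frac in spectrum:
                start, end = ann.start + off5, ann.end + off3
                if start < 0 or end > len(hp.sequence) or end - start < 1:
                    continue
                rows.append({
                    "sequence": hp.sequence[start:end],
                    "hairpin_id": hp.hairpin_id, "mature_id": ann.mature_id,
                    "region": f"mature{arm}", "off5": off5, "off3": off3,
                    "isoform_frac": frac,
                    "true_class": trow["true_class"], "f_slow": trow["f_slow"],
                    "h_fast": trow["h_fast"], "h_slow": trow["h_slow"],
                    "abundance0": trow["abundance"] * frac,
                })
        if loop is not None and loop[1] - loop[0] >= 1:
            rows.append({
                "sequence": hp.sequence[loop[0]:loop[1]],
                "hairpin_id": hp.hairpin_id, "mature_id": "",
                "region": "loop", "off5": 0, "off3": 0, "isoform_frac": 1.0,
                "true_class": "loop", "f_slow": math.nan,
                "h_fast": math.nan, "h_slow": config.loop_halflife_h,
                "abundance0": config.loop_frac * hp_abund0,
            })
    expected = pd.DataFrame(rows, columns=[
        "sequence", "hairpin_id", "mature_id", "region", "off5", "off3",
        "isoform_frac", "true_class", "f_slow", "h_fast", "h_slow", "abundance0"])

    mature_mask = expected["region"].str.startswith("mature") if len(expected) else \
        pd.Series([], dtype=bool)
    total0 = float(expected.loc[mature_mask, "abundance0"].sum()) if len(expected) else 0.0

    samples = []
    for t in config.timepoints_h:
        for r in range(1, config.n_replicates + 1):
            samples.append({"sample_id": f"t{t:g}h_r{r}", "time_h": float(t),
                            "replicate": r})
    samples = pd.DataFrame(samples, columns=["sample_id", "time_h", "replicate"])

    # expected counts per isoform per sample (vectorized over rows)
    is_fast = (expected["true_class"] == "fast").to_numpy() if len(expected) else np.empty(0, bool)
    f_slow = np.nan_to_num(expected["f_slow"].to_numpy(float)) if len(expected) else np.empty(0)
    h_fast = expected["h_fast"].to_numpy(float) if len(expected) else np.empty(0)
    h_slow = expected["h_slow"].to_numpy(float) if len(expected) else np.empty(0)
    abund0 = expected["abundance0"].to_numpy(float) if len(expected) else np.empty(0)
    with np.errstate(divide="ignore"):
        inv_hf = np.where(np.isfinite(h_fast) & (h_fast > 0), 1.0 / h_fast, 0.0)
        inv_hs = np.where(np.isfinite(h_slow) & (h_slow > 0), 1.0 / h_slow, 0.0)
    exp_counts = {}
    for srow in samples.itertuples(index=False):
        t = srow.time_h
        if len(expected):
            slow_part = 2.0 ** (-t * inv_hs)
            fast_part = 2.0 ** (-t * inv_hf)
            remaining = np.where(is_fast,
                                 f_slow * slow_part + (1.0 - f_slow) * fast_part,
                                 slow_part)
            mu = config.depth * abund0 * remaining / total0
        else:
            mu = np.empty(0)
        exp_counts[srow.sample_id] = mu

    seq_index = list(expected["sequence"])
    counts = {}
    for sample_id, mu in exp_counts.items():
        expected[sample_id] = mu
        counts[sample_id] = _draw_counts(rng, mu, config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=seq_index, dtype=np.int64)
    counts_df.index.name = "sequence"
    counts_df = counts_df.groupby(level=0, sort=True).sum()
    return SimulatedTimecourse(counts=counts_df, expected=expected,
                               samples=samples, reference=reference, spikeins={})


def _draw_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def add_spikein_counts(sim: SimulatedTimecourse, spikeins: dict,
                       config: SimConfig) -> SimulatedTimecourse:
    """Append constant-expectation spike-in reads to a simulated time course."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mu = config.spikein_frac * config.depth
    rows = {}
    for name in sorted(spikeins):
        seq = spikeins[name]
        rows[seq] = _draw_counts(
            rng, np.full(len(sim.samples), mu), config.nb_dispersion)
    add = pd.DataFrame(rows, index=sim.samples["sample_id"]).T.astype(np.int64)
    add.columns = sim.counts.columns if len(sim.counts.columns) else add.columns
    add.index.name = "sequence"
    sim.counts = pd.concat([sim.counts, add]).groupby(level=0, sort=True).sum()
    sim.spikeins = dict(spikeins)
    return sim


def write_reads(sim: SimulatedTimecourse, out_dir) -> dict:
    """Expand the count table to one-record-per-read FASTA files per sample.

    Returns {sample_id: path}. Intended for modest depths; at full depth
    the count-table interface is the practical route.
    """
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample_id in sim.counts.columns:
        path = out_dir / f"{sample_id}.fa"
        with open(path, "w") as fh:
            i = 0
            for seq, c in sim.counts[sample_id].items():
                for _ in range(int(c)):
                    fh.write(f">{sample_id}_{i}\n{seq}\n")
                    i += 1
        paths[sample_id] = path
    return paths


def simulate_profiling_matrix(config: SimConfig, truth: pd.DataFrame | None = None
                              ) -> SimulatedProfiling:
    """Simulate a bead-array profiling matrix with spike-in probe rows.

    ``intensity = scale_s * expected_abundance * lognormal noise`` with a
    per-sample scale factor; three spike-in rows are ``scale_s * constant``.
    When ``truth`` is omitted a reference is generated from the config.
    """
    config.validate()
    if truth is None:
        _, _, truth = generate_reference(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    samples = []
    for t in config.profiling_timepoints_h:
        for r in range(1, config.profiling_replicates + 1):
            samples.append({"sample_id": f"p{t:g}h_r{r}", "time_h": float(t),
                            "replicate": r})
    samples = pd.DataFrame(samples, columns=["sample_id", "time_h", "replicate"])

    probe_ids = list(truth["mature_id"]) + ["spike-1", "spike-2", "spike-3",
                                            "ctrl-1", "ctrl-2"]
    classes = (["mature"] * len(truth) + ["spikein"] * 3 + ["control"] * 2)
    probe_class = pd.Series(classes, index=probe_ids, name="probe_class")

    spike_level = 100.0
    ctrl_level = 50.0
    expected = {}
    for srow in samples.itertuples(index=False):
        col = [row["abundance"] * species_remaining(row, srow.time_h)
               for _, row in truth.iterrows()]
        col += [spike_level] * 3 + [ctrl_level] * 2
        expected[srow.sample_id] = col
    expected = pd.DataFrame(expected, index=probe_ids)

    scale_vals = rng.lognormal(0.0, config.profiling_scale_sigma, size=len(samples))
    # geometric-mean-1 convention makes spike-in normalization an exact inverse
    scale_vals /= np.exp(np.log(scale_vals).mean())
    scale = pd.Series(scale_vals, index=samples["sample_id"], name="scale_factor")
    noise = (rng.lognormal(0.0, config.profiling_noise_sigma, size=expected.shape)
             if config.profiling_noise_sigma > 0 else np.ones(expected.shape))
    matrix = expected * noise * scale

    return SimulatedProfiling(matrix=matrix, probe_class=probe_class,
                              samples=samples, scale_factors=scale,
                              expected=expected)


def write_simulation(reference, spikeins, truth, sim, out_dir) -> None:
    """Write reference FASTA/annotation, spike-ins, truth, counts and sample sheet."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_reference(reference, out_dir / "hairpins.fa", out_dir / "annotation.tsv")
    write_fasta(spikeins, out_dir / "spikeins.fa")
    truth.to_csv(out_dir / "truth_species.tsv", sep="\t", index=False)
    sim.samples.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    sim.counts.to_csv(out_dir / "counts.tsv", sep="\t")
    meta_cols = ["sequence", "hairpin_id", "mature_id", "region", "off5", "off3",
                 "isoform_frac", "true_class", "f_slow", "h_fast", "h_slow"]
    sim.expected[meta_cols].to_csv(out_dir / "truth_isoforms.tsv", sep="\t", index=False)
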