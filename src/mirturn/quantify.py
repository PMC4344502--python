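"""Assign reads to hairpin regions by exact match and count isoforms.

Mapping is exact substring matching against the hairpin reference
(pass 1, zero mismatches, reads >= 15 nt), with an optional second pass
that rescues reads whose only mismatches are 1-2 non-templated bases at
the 3' end (NTA). Region attribution follows the read's footprint on the
precursor: a mature arm if at least ``mature_overlap`` of the read lies
within the annotated mature interval extended by ``mature_window`` nt on
each side, the loop if fully inside the inter-arm interval, otherwise
"other".

Counting is per unique read sequence. A sequence matching several
hairpins is credited once per distinct mature-sequence group and flagged
multimapped; per-sample mature-mapped totals count each read exactly
once, and those totals are the normalization denominator for
frequencies.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .reference import Reference, canonicalize

META_COLS = ["sequence", "group_id", "mature_id", "hairpin_id", "region",
             "off5", "off3", "nta", "multimapped"]


class QuantifyError(ValueError):
    pass


@dataclass
class IsoformCountTable:
    """Per unique-sequence counts per sample plus bookkeeping tallies."""

    table: pd.DataFrame            # META_COLS + one count column per sample
    samples: list
    mature_mapped_total: pd.Series  # per sample, each read counted once
    discarded_short: pd.Series
    unassigned: pd.Series

    def counts(self) -> pd.DataFrame:
        return self.table[self.samples]


class _SeedIndex:
    """k-mer seeded exact-substring lookup over all hairpins."""

    def __init__(self, reference: Reference, k: int):
        self.k = k
        self.reference = reference
        self.seeds = defaultdict(list)
        for hp in reference:
            seq = hp.sequence
            for pos in range(len(seq) - k + 1):
                self.seeds[seq[pos:pos + k]].append((hp, pos))

    def matches(self, read: str):
        """All (hairpin, start) where the full read occurs exactly."""
        out = []
        for hp, pos in self.seeds.get(read[:self.k], ()):
            if hp.sequence.startswith(read, pos):
                out.append((hp, pos))
        return out

    def prefix_matches(self, prefix: str):
        return self.matches(prefix)


def classify_region(hp, pos: int, length: int, thresholds: ThresholdConfig):
    """Attribute a footprint [pos, pos+length) on ``hp`` to a region.

    Returns (region, mature_annotation_or_None). Mature arms win when the
    overlap fraction with the window-extended interval reaches the
    threshold (ties broken toward 5p); otherwise loop requires full
    containment; otherwise "other".
    """
    w = thresholds.mature_window
    best = None
    for arm in ("5p", "3p"):
        if arm not in hp.mature:
            continue
        ann = hp.mature[arm]
        lo, hi = ann.start - w, ann.end + w
        overlap = min(hi, pos + length) - max(lo, pos)
        frac = max(overlap, 0) / length
        if frac >= thresholds.mature_overlap and (best is None or frac > best[0]):
            best = (frac, arm, ann)
    if best is not None:
        return f"mature{best[1]}", best[2]
    loop = hp.loop
    if loop is not None and pos >= loop[0] and pos + length <= loop[1]:
        return "loop", None
    return "other", None


def _reads_to_counts(reads, samples=None) -> pd.DataFrame:
    """Normalize the reads argument to a sequence x sample count frame."""
    if isinstance(reads, pd.DataFrame):
        counts = reads.copy()
        counts.index = [canonicalize(s) for s in counts.index]
        return counts.groupby(level=0, sort=True).sum()
    per_sample = {}
    for sample_id, seqs in reads.items():
        tally = defaultdict(int)
        for s in seqs:
            tally[canonicalize(s)] += 1
        per_sample[sample_id] = tally
    all_seqs = sorted(set().union(*[set(t) for t in per_sample.values()] or [set()]))
    return pd.DataFrame(
        {sid: [per_sample[sid].get(s, 0) for s in all_seqs] for sid in per_sample},
        index=all_seqs, dtype=np.int64)


def quantify_reads(reads, reference: Reference,
                   thresholds: ThresholdConfig | None = None,
                   nta: bool = False) -> IsoformCountTable:
    """Count isoforms per sample by exact matching against the reference.

    ``reads`` is either a mapping ``{sample_id: iterable of sequences}``
    or a pre-collapsed DataFrame of counts indexed by read sequence with
    one column per sample. Set ``nta=True`` to run the 3' non-templated
    addition rescue pass on otherwise-unmapped reads.
    """
    thresholds = thresholds or ThresholdConfig()
    thresholds.validate()
    if len(reference) == 0:
        raise QuantifyError("empty reference")
    counts = _reads_to_counts(reads)
    samples = list(counts.columns)
    index = _SeedIndex(reference, thresholds.min_read_len)

    rows = []
    mat = counts.to_numpy()
    totals = np.zeros(len(samples), dtype=np.int64)
    short = np.zeros(len(samples), dtype=np.int64)
    unassigned = np.zeros(len(samples), dtype=np.int64)

    for i, seq in enumerate(counts.index):
        cvec = mat[i]
        if len(seq) < thresholds.min_read_len:
            short += cvec
            continue
        assignments = _assign(seq, index, reference, thresholds,
                              nta_allowed=nta)
        if not assignments:
            unassigned += cvec
            continue
        multimapped = len(assignments) > 1
        if any(a["region"].startswith("mature") for a in assignments):
            totals += cvec
        for a in assignments:
            row = {**a, "sequence": seq, "multimapped": multimapped}
            row.update(zip(samples, (int(c) for c in cvec)))
            rows.append(row)

    totals = pd.Series(totals, index=samples)
    short = pd.Series(short, index=samples)
    unassigned = pd.Series(unassigned, index=samples)

    table = pd.DataFrame(rows, columns=META_COLS + samples)
    if len(table):
        table = table.sort_values(["sequence", "group_id", "region"],
                                  kind="mergesort").reset_index(drop=True)
    return IsoformCountTable(table=table, samples=samples,
                             mature_mapped_total=totals,
                             discarded_short=short, unassigned=unassigned)


def _assign(seq, index: _SeedIndex, reference: Reference,
            thresholds: ThresholdConfig, nta_allowed: bool):
    """Distinct assignment records for one read sequence (may be empty)."""
    matches = [(hp, pos, len(seq), "") for hp, pos in index.matches(seq)]
    if not matches and nta_allowed:
        matches = _nta_matches(seq, index, thresholds)
    if not matches:
        return []
    groups = {}
    for hp, pos, length, nta_suffix in matches:
        region, ann = classify_region(hp, pos, length, thresholds)
        if ann is not None:
            group = reference.group_of.get(ann.mature_id, ann.mature_id)
            key = ("m", group, region, nta_suffix)
            rec = {"group_id": group, "mature_id": ann.mature_id,
                   "hairpin_id": hp.hairpin_id, "region": region,
                   "off5": pos - ann.start, "off3": (pos + length) - ann.end,
                   "nta": nta_suffix}
        else:
            key = ("r", hp.hairpin_id, region, nta_suffix)
            rec = {"group_id": "", "mature_id": "", "hairpin_id": hp.hairpin_id,
                   "region": region, "off5": 0, "off3": 0, "nta": nta_suffix}
        groups.setdefault(key, rec)
    return [groups[k] for k in sorted(groups)]


def _nta_matches(seq, index: _SeedIndex, thresholds: ThresholdConfig):
    """Pass-2 matches: exact prefix + <=max_nta mismatching terminal bases."""
    for k in range(1, thresholds.max_nta + 1):
        prefix = seq[:-k]
        if len(prefix) < thresholds.min_read_len:
            break
        out = []
        for hp, pos in index.prefix_matches(prefix):
            # the base right after the prefix must be non-templated
            j = pos + len(prefix)
            if j >= len(hp.sequence) or hp.sequence[j] != seq[len(prefix)]:
                out.append((hp, pos, len(prefix), seq[-k:]))
        if out:
            return out
    return []


@dataclass
class FrequencyMatrix:
    """Normalized frequencies (reads per total mature-mapped reads)."""

    isoform: pd.DataFrame        # index: isoform_id; columns: samples
    isoform_meta: pd.DataFrame   # same index; sequence/group/region/...
    entity: pd.DataFrame         # mature-aggregated (and per-hairpin loop) level
    entity_meta: pd.DataFrame
    samples: pd.DataFrame        # sample_id, time_h, replicate
    detected_isoform: pd.Series
    detected_entity: pd.Series
    theta: float


def compute_frequencies(counts: IsoformCountTable, sample_sheet: pd.DataFrame,
                        thresholds: ThresholdConfig | None = None) -> FrequencyMatrix:
    """Per-sample frequencies f = count / mature-mapped total.

    Frequencies are computed at the isoform level and aggregated to the
    mature level (loop rows aggregate per hairpin as ``<hairpin>:loop``);
    "other"-region rows are excluded from the entity level. The
    detection flag requires mean 0-h frequency >= theta; undetected
    entries are retained in the output but flagged for exclusion from
    downstream statistics.
    """
    thresholds = thresholds or ThresholdConfig()
    sample_sheet = sample_sheet.set_index("sample_id", drop=False) \
        if "sample_id" in sample_sheet.columns else sample_sheet
    samples = [s for s in counts.samples]
    missing = [s for s in samples if s not in set(sample_sheet.index)]
    if missing:
        raise QuantifyError(f"samples missing from sample sheet: {missing}")
    sheet = sample_sheet.loc[samples]
    zero_h = [s for s in samples if sheet.loc[s, "time_h"] == 0]
    if not zero_h:
        raise QuantifyError("no 0-h samples present")
    for s in samples:
        if counts.mature_mapped_total[s] <= 0:
            raise QuantifyError(f"sample {s!r} has zero mature-mapped reads")

    table = counts.table
    iso_ids = [f"{r.group_id or r.hairpin_id}|{r.region}|{r.sequence}"
               + (f"+{r.nta}" if r.nta else "")
               for r in table.itertuples(index=False)]
    iso_counts = table[samples].copy()
    iso_counts.index = iso_ids
    freq = iso_counts / counts.mature_mapped_total

    meta = table[META_COLS].copy()
    meta.index = iso_ids
    entity_id = np.where(meta["region"].str.startswith("mature"),
                         meta["group_id"],
                         meta["hairpin_id"] + ":" + meta["region"])
    meta["entity_id"] = entity_id

    keep = meta["region"] != "other"
    ent_freq = freq[keep].groupby(meta.loc[keep, "entity_id"]).sum()
    ent_meta = (meta[keep].groupby("entity_id")
                .agg(region=("region", "first"), hairpin_id=("hairpin_id", "first"),
                     n_isoforms=("sequence", "size")))

    det_iso = freq[zero_h].mean(axis=1) >= thresholds.detect_threshold
    det_ent = ent_freq[zero_h].mean(axis=1) >= thresholds.detect_threshold
    return FrequencyMatrix(isoform=freq, isoform_meta=meta,
                           entity=ent_freq, entity_meta=ent_meta,
                           samples=sheet, detected_isoform=det_iso,
                           detected_entity=det_ent,
                           theta=thresholds.detect_threshold)


def annotate_star(freqs: FrequencyMatrix, reference: Reference) -> pd.DataFrame:
    """Empirical star/non-star strand roles from mean 0-h frequencies.

    For two-arm hairpins the more abundant arm at 0 h is non-star and the
    other star; single-arm hairpins are non-star. An exact tie is broken
    toward 5p = non-star and flagged ambiguous.
    """
    zero_h = [s for s in freqs.samples.index if freqs.samples.loc[s, "time_h"] == 0]
    mean0 = freqs.entity[zero_h].mean(axis=1)
    rows = []
    for hp in reference:
        arm_freq = {}
        for arm in ("5p", "3p"):
            if arm in hp.mature:
                gid = reference.group_of[hp.mature[arm].mature_id]
                arm_freq[arm] = float(mean0.get(gid, 0.0))
        if not arm_freq:
            continue
        if len(arm_freq) == 1:
            arm = next(iter(arm_freq))
            rows.append(_star_row(hp, arm, "non_star", arm_freq[arm], False,
                                  reference))
            continue
        f5, f3 = arm_freq["5p"], arm_freq["3p"]
        ambiguous = f5 == f3
        nonstar = "5p" if f5 >= f3 else "3p"
        star = "3p" if nonstar == "5p" else "5p"
        rows.append(_star_row(hp, nonstar, "non_star", arm_freq[nonstar],
                              ambiguous, reference))
        rows.append(_star_row(hp, star, "star", arm_freq[star], ambiguous,
                              reference))
    return pd.DataFrame(rows, columns=["hairpin_id", "mature_id", "group_id",
                                       "arm", "role", "mean_freq_0h",
                                       "ambiguous"])


def _star_row(hp, arm, role, f0, ambiguous, reference):
    mid = hp.mature[arm].mature_id
    return {"hairpin_id": hp.hairpin_id, "mature_id": mid,
            "group_id": reference.group_of[mid], "arm": arm, "role": role,
            "mean_freq_0h": f0, "ambiguous": ambiguous}
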