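"""Reference loading, read assignment, frequencies and star annotation."""

import numpy as np
import pandas as pd
import pytest

from mirturn import ThresholdConfig, annotate_star, compute_frequencies, quantify_reads
from mirturn.quantify import QuantifyError
from mirturn.reference import (HairpinRecord, MatureAnnotation, Reference,
                               ReferenceError, load_reference, write_reference)

TH = ThresholdConfig()


# ---------------------------------------------------------------- reference

def test_loop_interval_is_derived_between_arms():
    hp = HairpinRecord("h", "A" * 80, {
        "5p": MatureAnnotation("m5", "5p", 6, 28),
        "3p": MatureAnnotation("m3", "3p", 50, 72)})
    assert hp.loop == (28, 50)


def test_annotation_referencing_absent_hairpin_errors(tmp_path, toy_reference):
    write_reference(toy_reference, tmp_path / "h.fa", tmp_path / "a.tsv")
    annot = pd.read_csv(tmp_path / "a.tsv", sep="\t")
    annot.loc[0, "hairpin_id"] = "nonexistent"
    annot.to_csv(tmp_path / "bad.tsv", sep="\t", index=False)
    with pytest.raises(ReferenceError, match="unknown hairpin"):
        load_reference(tmp_path / "h.fa", tmp_path / "bad.tsv")


def test_out_of_bounds_interval_and_bad_alphabet_error():
    with pytest.raises(ReferenceError, match="outside hairpin"):
        Reference([HairpinRecord("h", "ACGT" * 10, {
            "5p": MatureAnnotation("m", "5p", 30, 55)})])
    with pytest.raises(ReferenceError, match="non-ACGTU"):
        Reference([HairpinRecord("h", "ACGTN", {})])


def test_rna_fasta_round_trips_through_u_to_t(tmp_path, toy_reference):
    hp = toy_reference.hairpins[0]
    rna = hp.sequence.replace("T", "U")
    (tmp_path / "rna.fa").write_text(f">hp-toy\n{rna}\n")
    write_reference(toy_reference, tmp_path / "dna.fa", tmp_path / "a.tsv")
    ref = load_reference(tmp_path / "rna.fa", tmp_path / "a.tsv")
    assert ref.by_id["hp-toy"].sequence == hp.sequence
    assert ref.by_id["hp-toy"].mature_seq("5p") == hp.mature_seq("5p")
    # writer restores the original alphabet
    write_reference(ref, tmp_path / "back.fa", tmp_path / "b.tsv")
    body = "".join((tmp_path / "back.fa").read_text().splitlines()[1:])
    assert body == rna


# ---------------------------------------------------------------- assignment

def test_exact_mature_read_gets_zero_offsets(toy_reference):
    hp = toy_reference.hairpins[0]
    reads = {"s": [hp.mature_seq("5p")]}
    t = quantify_reads(reads, toy_reference)
    row = t.table.iloc[0]
    assert (row["region"], row["off5"], row["off3"], row["nta"]) == \
        ("mature5p", 0, 0, "")
    assert t.mature_mapped_total["s"] == 1


def test_nta_read_rescued_in_pass_two_only(toy_reference):
    hp = toy_reference.hairpins[0]
    m3p = hp.mature_seq("3p")
    after = hp.sequence[hp.mature["3p"].end]      # templated next base
    nta_base = "A" if after != "A" else "C"
    read = m3p + nta_base
    t_off = quantify_reads({"s": [read]}, toy_reference, nta=False)
    assert len(t_off.table) == 0 and t_off.unassigned["s"] == 1
    t_on = quantify_reads({"s": [read]}, toy_reference, nta=True)
    row = t_on.table.iloc[0]
    assert row["nta"] == nta_base and row["region"] == "mature3p"
    assert row["off3"] == 0        # offsets refer to the templated footprint


def test_short_reads_are_tallied_not_counted(toy_reference):
    t = quantify_reads({"s": ["ACGTACGTACGT"]}, toy_reference)
    assert t.discarded_short["s"] == 1
    assert len(t.table) == 0


def test_empty_reference_is_an_error():
    with pytest.raises(QuantifyError, match="empty reference"):
        quantify_reads({"s": ["A" * 20]}, Reference([]))


def test_loop_read_classified_by_full_containment(toy_reference):
    hp = toy_reference.hairpins[0]
    loop_seq = hp.sequence[hp.loop[0]:hp.loop[1]]
    t = quantify_reads({"s": [loop_seq]}, toy_reference)
    assert t.table.iloc[0]["region"] == "loop"
    assert t.mature_mapped_total["s"] == 0


def _scan_positions(seq, reference):
    out = []
    for hp in reference:
        for pos in range(len(hp.sequence) - len(seq) + 1):
            if hp.sequence[pos:pos + len(seq)] == seq:
                out.append((hp, pos))
    return out


def _oracle_table(reads_by_sample, reference, th):
    """Exhaustive position-scan oracle with independent overlap arithmetic."""
    samples = list(reads_by_sample)
    rows = {}
    totals = {s: 0 for s in samples}
    for s in samples:
        for seq in reads_by_sample[s]:
            if len(seq) < th.min_read_len:
                continue
            keys = set()
            for hp, pos in _scan_positions(seq, reference):
                best = None
                for arm in ("5p", "3p"):
                    if arm not in hp.mature:
                        continue
                    ann = hp.mature[arm]
                    lo, hi = ann.start - th.mature_window, ann.end + th.mature_window
                    ov = min(hi, pos + len(seq)) - max(lo, pos)
                    frac = max(ov, 0) / len(seq)
                    if frac >= th.mature_overlap and (best is None or frac > best[0]):
                        best = (frac, arm, ann)
                if best is not None:
                    gid = reference.group_of[best[2].mature_id]
                    keys.add((seq, gid, f"mature{best[1]}"))
                elif hp.loop and pos >= hp.loop[0] and pos + len(seq) <= hp.loop[1]:
                    keys.add((seq, hp.hairpin_id, "loop"))
                else:
                    keys.add((seq, hp.hairpin_id, "other"))
            if any(k[2].startswith("mature") for k in keys):
                totals[s] += 1
            for k in keys:
                rows.setdefault(k, {t: 0 for t in samples})[s] += 1
    return rows, totals


def test_counts_match_exhaustive_scan_oracle(small_sim):
    cfg, ref, _, _, sim = small_sim
    # build a modest read multiset from the count table (two samples)
    samples = ["t0h_r1", "t12h_r1"]
    reads = {}
    for s in samples:
        expanded = []
        for seq, c in sim.counts[s].items():
            expanded.extend([seq] * min(int(c), 3))
        reads[s] = expanded
    assert sum(len(v) for v in reads.values()) <= 5000
    t = quantify_reads(reads, ref)
    oracle_rows, oracle_totals = _oracle_table(reads, ref, TH)
    got = {(r.sequence, r.group_id or r.hairpin_id, r.region):
           {s: getattr(r, s) for s in samples}
           for r in t.table.itertuples(index=False)}
    assert got == oracle_rows
    assert t.mature_mapped_total.to_dict() == oracle_totals


def test_read_order_never_changes_counts(small_sim):
    _, ref, _, _, sim = small_sim
    seqs = []
    for seq, c in sim.counts["t0h_r1"].items():
        seqs.extend([seq] * min(int(c), 2))
    rng = np.random.default_rng(0)
    shuffled = list(rng.permutation(seqs))
    t1 = quantify_reads({"s": seqs}, ref)
    t2 = quantify_reads({"s": shuffled}, ref)
    pd.testing.assert_frame_equal(t1.table, t2.table)


# ---------------------------------------------------------------- frequencies

def test_frequencies_are_counts_over_mature_total(toy_reference):
    hp = toy_reference.hairpins[0]
    reads = {"s": [hp.mature_seq("5p")] * 5 + [hp.mature_seq("3p")] * 95}
    sheet = pd.DataFrame({"sample_id": ["s"], "time_h": [0.0], "replicate": [1]})
    fm = compute_frequencies(quantify_reads(reads, toy_reference), sheet)
    assert fm.entity.loc["toy-5p", "s"] == pytest.approx(0.05)
    assert fm.entity.loc["toy-3p", "s"] == pytest.approx(0.95)


def test_detection_threshold_is_five_per_million(toy_reference):
    hp = toy_reference.hairpins[0]
    counts = pd.DataFrame({"s": [4, 999_996]},
                          index=[hp.mature_seq("5p"), hp.mature_seq("3p")])
    sheet = pd.DataFrame({"sample_id": ["s"], "time_h": [0.0], "replicate": [1]})
    fm = compute_frequencies(quantify_reads(counts, toy_reference), sheet)
    assert fm.entity.loc["toy-5p", "s"] == pytest.approx(4e-6)
    assert not fm.detected_entity["toy-5p"]       # 4e-6 < theta
    assert fm.detected_entity["toy-3p"]
    at_theta = pd.DataFrame({"s": [5, 999_995]}, index=counts.index)
    fm2 = compute_frequencies(quantify_reads(at_theta, toy_reference), sheet)
    assert fm2.detected_entity["toy-5p"]          # exactly theta -> detected


def test_mature_isoform_frequencies_sum_to_one(small_fm):
    counts, fm = small_fm
    mature = fm.isoform_meta["region"].str.startswith("mature")
    sums = fm.isoform[mature].sum()
    np.testing.assert_allclose(sums, 1.0, rtol=1e-12)


def test_frequencies_invariant_to_uniform_scaling(small_sim):
    _, ref, _, _, sim = small_sim
    t1 = quantify_reads(sim.counts, ref)
    t2 = quantify_reads(sim.counts * 3, ref)
    fm1 = compute_frequencies(t1, sim.samples)
    fm2 = compute_frequencies(t2, sim.samples)
    pd.testing.assert_frame_equal(fm1.isoform, fm2.isoform)


def test_zero_mature_reads_in_sample_is_an_error(toy_reference):
    hp = toy_reference.hairpins[0]
    counts = pd.DataFrame({"s0": [10], "s1": [0]}, index=[hp.mature_seq("5p")])
    sheet = pd.DataFrame({"sample_id": ["s0", "s1"], "time_h": [0.0, 4.0],
                          "replicate": [1, 1]})
    with pytest.raises(QuantifyError, match="s1"):
        compute_frequencies(quantify_reads(counts, toy_reference), sheet)


# ---------------------------------------------------------------- star strands

def _fm_from_counts(reference, counts, sheet):
    return compute_frequencies(quantify_reads(counts, reference), sheet)


def test_star_annotation_by_zero_hour_abundance(toy_reference):
    hp = toy_reference.hairpins[0]
    counts = pd.DataFrame({"s": [100, 1000]},
                          index=[hp.mature_seq("5p"), hp.mature_seq("3p")])
    sheet = pd.DataFrame({"sample_id": ["s"], "time_h": [0.0], "replicate": [1]})
    star = annotate_star(_fm_from_counts(toy_reference, counts, sheet),
                         toy_reference)
    roles = star.set_index("arm")["role"]
    assert roles["3p"] == "non_star" and roles["5p"] == "star"
    assert not star["ambiguous"].any()


def test_single_arm_hairpin_is_non_star():
    m = "TGAGGTAGTAGGTTGTATAGTT"
    hp = HairpinRecord("h1", "ACGTAC" + m + "GGGTTTGGGTTTGGGTACCGTA",
                       {"5p": MatureAnnotation("m1", "5p", 6, 28)})
    ref = Reference([hp])
    counts = pd.DataFrame({"s": [10]}, index=[m])
    sheet = pd.DataFrame({"sample_id": ["s"], "time_h": [0.0], "replicate": [1]})
    star = annotate_star(_fm_from_counts(ref, counts, sheet), ref)
    assert list(star["role"]) == ["non_star"]


def test_equal_strands_tie_break_to_5p_with_flag(toy_reference):
    hp = toy_reference.hairpins[0]
    counts = pd.DataFrame({"s": [50, 50]},
                          index=[hp.mature_seq("5p"), hp.mature_seq("3p")])
    sheet = pd.DataFrame({"sample_id": ["s"], "time_h": [0.0], "replicate": [1]})
    star = annotate_star(_fm_from_counts(toy_reference, counts, sheet),
                         toy_reference)
    roles = star.set_index("arm")
    assert roles.loc["5p", "role"] == "non_star"
    assert roles.loc["3p", "role"] == "star"
    assert star["ambiguous"].all()


def test_planted_strand_roles_recovered(small_sim, small_fm):
    _, ref, _, truth, _ = small_sim
    _, fm = small_fm
    star = annotate_star(fm, ref)
    merged = star.merge(truth, on="mature_id")
    assert (merged["role"] == merged["strand_role"]).all()
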