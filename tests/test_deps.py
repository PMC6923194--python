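"""M' statistics, the two DEP filter criteria, promoter assignment, tallies."""

import numpy as np
import pandas as pd
import pytest

import medipchip as mc
from medipchip.deps import (DEPTally, assign_promoter, filter_deps, group_cv,
                            probe_cv, region_mprime, tally)
from medipchip.peaks import Peak

from conftest import toy_design, toy_intensities

GROUPS = {"HF-CON": ["h1", "h2", "h3"], "CON-CON": ["c1", "c2", "c3"]}


def experiment_from_r(r: pd.DataFrame):
    m = toy_intensities(r, GROUPS)
    return m, mc.log_ratio(m)


def peak_of(design, probe_ids):
    sub = design.probes[design.probes["probe_id"].isin(probe_ids)]
    return Peak(chrom=sub["chrom"].iloc[0], start=int(sub["start"].min()),
                end=int(sub["end"].max()), probe_ids=tuple(probe_ids), score=3.0)


def test_mprime_constant_group_difference():
    design = toy_design([0, 100, 200])
    r = pd.DataFrame({s: [2.0] * 3 for s in GROUPS["HF-CON"]}
                     | {s: [0.5] * 3 for s in GROUPS["CON-CON"]},
                     index=design.probe_ids)
    _, enrich = experiment_from_r(r)
    peak = peak_of(design, list(design.probe_ids))
    assert region_mprime(peak, enrich) == pytest.approx(1.5)


def test_mprime_identical_groups_is_zero():
    design = toy_design([0, 100])
    r = pd.DataFrame({s: [1.0, 2.0] for s in GROUPS["HF-CON"] + GROUPS["CON-CON"]},
                     index=design.probe_ids)
    _, enrich = experiment_from_r(r)
    assert region_mprime(peak_of(design, list(design.probe_ids)), enrich) == 0.0


def test_mprime_matches_flat_mean_oracle():
    rng = np.random.default_rng(2)
    design = toy_design([0, 100, 200])
    r = pd.DataFrame(rng.normal(size=(3, 6)),
                     index=design.probe_ids,
                     columns=GROUPS["HF-CON"] + GROUPS["CON-CON"])
    _, enrich = experiment_from_r(r)
    got = region_mprime(peak_of(design, list(design.probe_ids)), enrich)
    vals = r.to_numpy()
    oracle = vals[:, :3].ravel().mean() - vals[:, 3:].ravel().mean()
    assert got == pytest.approx(oracle, abs=1e-12)


def test_cv_identical_replicates_is_zero(small_experiment):
    design = toy_design([0])
    r = pd.DataFrame({s: [1.3] for s in GROUPS["HF-CON"] + GROUPS["CON-CON"]},
                     index=design.probe_ids)
    m, _ = experiment_from_r(r)
    assert probe_cv(m, "t000", "HF-CON") == pytest.approx(0.0)


def test_cv_two_point_formula():
    # ratios {1, 3}: sd = sqrt(2), mean = 2 -> CV = sqrt(2)/2
    idx = pd.Index(["p"], name="probe_id")
    samples = pd.DataFrame({"group": ["A", "A"], "replicate": [1, 2]},
                           index=pd.Index(["s1", "s2"], name="sample_id"))
    m = mc.IntensityMatrix(
        medip=pd.DataFrame({"s1": [10.0], "s2": [30.0]}, index=idx),
        input_=pd.DataFrame({"s1": [10.0], "s2": [10.0]}, index=idx),
        samples=samples)
    assert probe_cv(m, "p", "A") == pytest.approx(np.sqrt(2) / 2)


def test_cv_single_replicate_fails():
    idx = pd.Index(["p"], name="probe_id")
    samples = pd.DataFrame({"group": ["A"], "replicate": [1]},
                           index=pd.Index(["s1"], name="sample_id"))
    m = mc.IntensityMatrix(medip=pd.DataFrame({"s1": [1.0]}, index=idx),
                           input_=pd.DataFrame({"s1": [1.0]}, index=idx),
                           samples=samples)
    with pytest.raises(ValueError, match="fewer than 2"):
        probe_cv(m, "p", "A")


def test_cv_random_triples_match_sd_over_mean_oracle():
    rng = np.random.default_rng(8)
    idx = pd.Index([f"p{i}" for i in range(50)], name="probe_id")
    samples = pd.DataFrame({"group": ["A"] * 3, "replicate": [1, 2, 3]},
                           index=pd.Index(["s1", "s2", "s3"], name="sample_id"))
    medip = pd.DataFrame(rng.uniform(1, 100, (50, 3)), index=idx,
                         columns=["s1", "s2", "s3"])
    input_ = pd.DataFrame(rng.uniform(1, 100, (50, 3)), index=idx,
                          columns=["s1", "s2", "s3"])
    m = mc.IntensityMatrix(medip=medip, input_=input_, samples=samples)
    cv = group_cv(m, "A")
    ratios = (medip / input_).to_numpy()
    oracle = ratios.std(axis=1, ddof=1) / ratios.mean(axis=1)
    np.testing.assert_allclose(cv.to_numpy(), oracle, atol=1e-12)


def test_filter_rejects_low_medians():
    design = toy_design([0, 100])
    r = pd.DataFrame({s: [0.1, 0.1] for s in GROUPS["HF-CON"] + GROUPS["CON-CON"]},
                     index=design.probe_ids)
    m, enrich = experiment_from_r(r)
    assert filter_deps([peak_of(design, list(design.probe_ids))], enrich, m) == []


def test_filter_accepts_clear_hyper_peak():
    design = toy_design([0, 100])
    r = pd.DataFrame({s: [1.1, 1.3] for s in GROUPS["HF-CON"]}
                     | {s: [0.0, -0.1] for s in GROUPS["CON-CON"]},
                     index=design.probe_ids)
    m, enrich = experiment_from_r(r)
    deps = filter_deps([peak_of(design, list(design.probe_ids))], enrich, m)
    assert len(deps) == 1
    assert deps[0].direction == "hyper"
    assert deps[0].mprime == pytest.approx(1.25)


def test_filter_matches_brute_force_predicate():
    """200 randomized peaks vs an independently coded row-by-row predicate."""
    rng = np.random.default_rng(77)
    n_probes = 600
    design = toy_design(np.arange(n_probes) * 100)
    cols = GROUPS["HF-CON"] + GROUPS["CON-CON"]
    r = pd.DataFrame(rng.normal(0.3, 0.6, (n_probes, 6)), index=design.probe_ids,
                     columns=cols)
    m = toy_intensities(r, GROUPS)
    # perturb channel levels so linear CVs vary independently of r
    m = mc.IntensityMatrix(medip=m.medip * rng.uniform(0.5, 2.0, (n_probes, 1)),
                           input_=m.input_ * rng.uniform(0.5, 2.0, (n_probes, 1)),
                           samples=m.samples)
    enrich = mc.log_ratio(m)
    peaks = []
    for _ in range(200):
        i = int(rng.integers(0, n_probes - 6))
        width = int(rng.integers(2, 7))
        peaks.append(peak_of(design, [f"t{j:03d}" for j in range(i, i + width)]))
    got = filter_deps(peaks, enrich, m)
    got_keys = {(d.start, d.end): d.direction for d in got}

    # independent predicate straight from the criteria (recomputing the
    # log ratio from the perturbed channels with its own arithmetic)
    ratios = (m.medip / m.input_)
    r_obs = np.log2(m.medip) - np.log2(m.input_)
    accepted = {}
    for p in peaks:
        ids = list(p.probe_ids)
        meds, fracs = [], []
        for grp_cols in (GROUPS["HF-CON"], GROUPS["CON-CON"]):
            per_probe = r_obs.loc[ids, grp_cols].mean(axis=1)
            meds.append(float(np.median(per_probe)))
            rat = ratios.loc[ids, grp_cols].to_numpy()
            cv = rat.std(axis=1, ddof=1) / rat.mean(axis=1)
            fracs.append(float(np.mean(cv <= 0.8)))
        mprime = float(r_obs.loc[ids, GROUPS["HF-CON"]].to_numpy().mean()
                       - r_obs.loc[ids, GROUPS["CON-CON"]].to_numpy().mean())
        if max(meds) >= 0.3 and mprime != 0 and min(fracs) >= 0.5:
            accepted[(p.start, p.end)] = "hyper" if mprime > 0 else "hypo"
    assert got_keys == accepted
    # sorted by |M'| descending
    mags = [abs(d.mprime) for d in got]
    assert mags == sorted(mags, reverse=True)


def test_assign_single_and_spanning_promoters():
    rows = pd.DataFrame({
        "probe_id": ["a", "b", "c", "d"],
        "chrom": ["chr1"] * 4,
        "start": [0, 100, 200, 300], "end": [50, 150, 250, 350],
        "promoter_id": ["g1", "g1", "g2", "g2"]})
    design = mc.ProbeDesign(rows)
    classes = {"g1": "HCP", "g2": "LCP"}
    one = mc.DEP(peak=Peak("chr1", 0, 150, ("a", "b"), 3.0), mprime=1.0,
                 direction="hyper")
    two = mc.DEP(peak=Peak("chr1", 100, 250, ("b", "c"), 3.0), mprime=1.0,
                 direction="hyper")
    assert assign_promoter(one, design, classes).gene_ids == ("g1",)
    spanning = assign_promoter(two, design, classes)
    assert spanning.gene_ids == ("g1", "g2")
    assert spanning.cpg_class == "HCP"  # first promoter wins the 1-1 tie


def test_unique_genes_never_exceed_dep_count(small_experiment):
    promoters, design, m, truth = small_experiment
    deps = mc.run_differential_pipeline(m, design,
                                        promoter_classes=truth.promoter_classes)
    genes = {g for d in deps for g in d.gene_ids}
    assert len(genes) <= sum(len(d.gene_ids) for d in deps)
    assert all(d.gene_ids for d in deps)


def test_tally_from_published_style_counts():
    t = DEPTally.from_counts(hyper={"HCP": 487, "ICP": 158, "LCP": 68},
                             hypo={"HCP": 151, "ICP": 105, "LCP": 130})
    assert t.direction_total("hyper") == 713
    assert t.direction_total("hypo") == 386
    assert t.total == 1099
    pct = t.percentages("hyper")
    assert pct["HCP"] == pytest.approx(round(100 * 487 / 713, 2))
    assert sum(pct.values()) == pytest.approx(100.0, abs=0.05)


def test_empty_tally_has_no_division_by_zero():
    t = tally([])
    assert t.total == 0
    assert t.percentages("hyper") == {}
    assert "Total DEPs: 0" in t.report()


def test_tally_conservation_on_pipeline_output(small_experiment):
    promoters, design, m, truth = small_experiment
    deps = mc.run_differential_pipeline(m, design,
                                        promoter_classes=truth.promoter_classes)
    t = tally(deps)
    assert t.total == len(deps)
    for d in ("hyper", "hypo"):
        assert t.direction_total(d) == sum(t.by_class[d].values())
        assert t.direction_total(d) == sum(t.by_chrom[d].values())
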