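"""Reading, instrument selection, proxy substitution and harmonization."""

import itertools

import pytest

from mrlink import (
    ConfigurationError,
    InputError,
    InstrumentError,
    InstrumentSet,
    SummaryRecord,
    harmonize,
    read_summary_table,
    select_instruments,
    substitute_proxies,
)
from mrlink.gwas_summary import COMPLEMENT


def rec(vid, ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01, p=1e-9, **kw):
    return SummaryRecord(vid, ea, oa, eaf, beta, se, p, **kw)


# ---------------------------------------------------------------------------
# read_summary_table
# ---------------------------------------------------------------------------

HEADER = "variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\n"


def write(tmp_path, body, name="sumstats.tsv"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


def test_well_formed_table_reads_all_rows(tmp_path):
    path = write(tmp_path,
                 "rs1\tA\tG\t0.2\t0.1\t0.01\t1e-9\n"
                 "rs2\tC\tT\t0.4\t-0.2\t0.02\t1e-10\n"
                 "rs3\tG\tC\t0.6\t0.05\t0.01\t1e-8\n")
    records, drops = read_summary_table(path)
    assert len(records) == 3 and drops == []
    assert records[1].beta == -0.2


def test_non_positive_se_row_dropped_and_logged(tmp_path):
    path = write(tmp_path,
                 "rs1\tA\tG\t0.2\t0.1\t0.01\t1e-9\n"
                 "rs2\tC\tT\t0.4\t-0.2\t0\t1e-10\n")
    records, drops = read_summary_table(path)
    assert [r.variant_id for r in records] == ["rs1"]
    assert len(drops) == 1
    assert "row 2" in drops[0].detail and "non-positive SE" in drops[0].detail


def test_lowercase_alleles_are_normalized(tmp_path):
    path = write(tmp_path, "rs1\ta\tt\t0.2\t0.1\t0.01\t1e-9\n")
    records, _ = read_summary_table(path)
    assert (records[0].effect_allele, records[0].other_allele) == ("A", "T")


def test_missing_mandatory_column_is_configuration_error(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("variant_id\tbeta\nrs1\t0.1\n")
    with pytest.raises(ConfigurationError):
        read_summary_table(p)


def test_all_rows_invalid_is_input_error(tmp_path):
    path = write(tmp_path, "rs1\tA\tG\t0.2\t0.1\t-1\t1e-9\n")
    with pytest.raises(InputError):
        read_summary_table(path)


def test_column_map_and_csv_autodetect(tmp_path):
    p = tmp_path / "sumstats.csv"
    p.write_text("snp,ea,oa,freq,b,stderr,p\nrs1,A,G,0.2,0.1,0.01,1e-9\n")
    records, _ = read_summary_table(p, column_map={
        "variant_id": "snp", "effect_allele": "ea", "other_allele": "oa",
        "eaf": "freq", "beta": "b", "se": "stderr", "pvalue": "p"})
    assert records[0].variant_id == "rs1" and records[0].se == 0.01


# ---------------------------------------------------------------------------
# select_instruments
# ---------------------------------------------------------------------------

def test_exclusion_of_one_pleiotropic_variant_leaves_60():
    """A 61-instrument TSH-like set minus the one excluded locus is 60."""
    records = [rec(f"rs{j}") for j in range(61)]
    out = select_instruments(records, exclusion_list={"rs7"})
    assert len(out) == 60
    assert "rs7" not in out.variant_ids
    reasons = {e.variant_id: e.reason for e in out.provenance_log if e.action == "dropped"}
    assert reasons == {"rs7": "exclusion_list"}


def test_no_genome_wide_significant_record_is_instrument_error():
    records = [rec(f"rs{j}", p=0.5) for j in range(5)]
    with pytest.raises(InstrumentError, match="p-value"):
        select_instruments(records)


def brute_force_prune(records, ld, ld_max):
    """Independent oracle: lexicographically-first maximal feasible subset.

    Feasible = pairwise R^2 < ld_max.  Subsets are compared by their
    members' (pvalue, variant_id) sequences sorted ascending, which is the
    tie rule the greedy prune uses.
    """
    def ok(subset):
        return all(ld.get(frozenset((a.variant_id, b.variant_id)), 0.0) < ld_max
                   for a, b in itertools.combinations(subset, 2))

    feasible = [s for r in range(1, len(records) + 1)
                for s in itertools.combinations(records, r) if ok(s)]
    maximal = [s for s in feasible
               if not any(set(s) < set(t) for t in feasible)]
    key = lambda s: sorted((r.pvalue, r.variant_id) for r in s)
    return {r.variant_id for r in min(maximal, key=key)}


def test_greedy_ld_prune_matches_brute_force_oracle():
    records = [rec(f"rs{j}", p=p) for j, p in
               enumerate([1e-20, 1e-15, 1e-12, 1e-10, 1e-9])]
    ld = {frozenset(("rs0", "rs1")): 0.5, frozenset(("rs0", "rs2")): 0.5}
    out = select_instruments(records, ld_table=ld)
    assert len(out) == 3
    assert set(out.variant_ids) == brute_force_prune(records, ld, 0.01)


def test_ld_prune_brute_force_on_random_instances(rng):
    for trial in range(30):
        n = int(rng.integers(3, 8))
        records = [rec(f"rs{j}", p=float(rng.uniform(1e-30, 1e-8)))
                   for j in range(n)]
        ld = {}
        for a, b in itertools.combinations(range(n), 2):
            if rng.random() < 0.3:
                ld[frozenset((f"rs{a}", f"rs{b}"))] = float(rng.uniform(0.02, 1.0))
        out = select_instruments(records, ld_table=ld)
        assert set(out.variant_ids) == brute_force_prune(records, ld, 0.01)


def test_selection_is_independent_of_row_order(rng):
    records = [rec(f"rs{j}", p=float(rng.uniform(1e-30, 1e-8))) for j in range(8)]
    ld = {frozenset(("rs1", "rs3")): 0.9, frozenset(("rs2", "rs5")): 0.3}
    base = select_instruments(records, ld_table=ld)
    shuffled = list(records)
    rng.shuffle(shuffled)
    assert set(select_instruments(shuffled, ld_table=ld).variant_ids) == set(base.variant_ids)


def test_every_dropped_variant_logged_once_with_reason():
    records = [rec("rs_weak", p=0.5)] + [rec(f"rs{j}") for j in range(4)]
    ld = {frozenset(("rs0", "rs1")): 0.8}
    out = select_instruments(records, ld_table=ld, exclusion_list={"rs2"})
    dropped = [e for e in out.provenance_log if e.action == "dropped"]
    assert sorted(e.variant_id for e in dropped) == ["rs1", "rs2", "rs_weak"]
    assert {e.reason for e in dropped} == {
        "ld_prune", "exclusion_list", "pvalue_above_threshold"}


# ---------------------------------------------------------------------------
# substitute_proxies
# ---------------------------------------------------------------------------

def iset(records):
    return InstrumentSet("exposure", "per_sd", records)


def test_all_instruments_present_is_identity():
    s = iset([rec("rs1"), rec("rs2")])
    out = substitute_proxies(s, {"rs1", "rs2"}, {})
    assert out.variant_ids == ["rs1", "rs2"]


def test_partial_proxy_coverage_substitutes_and_drops():
    """Seven missing instruments, proxies for four: 4 swaps, 3 drops."""
    present = [rec(f"rs{j}") for j in range(3)]
    missing = [rec(f"rsm{j}") for j in range(7)]
    proxies = {f"rsm{j}": [(f"rsp{j}", 0.95, 1)] for j in range(4)}
    outcome_ids = {f"rs{j}" for j in range(3)} | {f"rsp{j}" for j in range(4)}
    out = substitute_proxies(iset(present + missing), outcome_ids, proxies)
    assert len(out) == 3 + 4
    subs = [e for e in out.provenance_log if e.action == "substituted"]
    drops = [e for e in out.provenance_log if e.reason == "no_proxy"]
    assert len(subs) == 4 and len(drops) == 3
    by_id = {r.variant_id: r for r in out.records}
    assert by_id["rsp0"].proxy_of == "rsm0"


def test_proxy_below_r2_threshold_not_used():
    s = iset([rec("rs1")])
    out = substitute_proxies(s, {"rsp1"}, {"rs1": [("rsp1", 0.85, 1)]})
    assert len(out) == 0
    assert out.provenance_log[-1].reason == "no_proxy"


def test_highest_r2_admissible_proxy_wins():
    s = iset([rec("rs1")])
    table = {"rs1": [("lo", 0.92, 1), ("hi", 0.98, -1), ("absent", 0.99, 1)]}
    out = substitute_proxies(s, {"lo", "hi"}, table)
    assert out.records[0].variant_id == "hi"
    assert out.records[0].proxy_sign == -1


# ---------------------------------------------------------------------------
# harmonize
# ---------------------------------------------------------------------------

def harmonize_one(exp, out, **kw):
    hs, log = harmonize(iset([exp]), [out], **kw)
    return hs[0]


def test_aligned_alleles_pass_through():
    h = harmonize_one(rec("rs1", "A", "G", beta=0.1),
                      rec("rs1", "A", "G", beta=0.05))
    assert (h.beta_x, h.beta_y, h.flipped) == (0.1, 0.05, False)


def test_swapped_outcome_alleles_negate_beta_y():
    h = harmonize_one(rec("rs1", "A", "G", beta=0.1),
                      rec("rs1", "G", "A", beta=0.05))
    assert (h.beta_y, h.flipped) == (-0.05, True)


def test_negative_exposure_beta_reoriented_to_increasing_allele():
    h = harmonize_one(rec("rs1", "A", "G", beta=-0.1, eaf=0.3),
                      rec("rs1", "A", "G", beta=0.05))
    assert h.beta_x == 0.1
    assert h.beta_y == -0.05  # outcome A allele is now the non-effect allele


def test_strand_complement_recognised():
    # exposure A/G vs outcome reported on the other strand as T/C
    h = harmonize_one(rec("rs1", "A", "G", beta=0.1),
                      rec("rs1", "T", "C", beta=0.05))
    assert (h.beta_y, h.flipped) == (0.05, False)


def test_irreconcilable_alleles_dropped():
    with pytest.raises(InstrumentError):
        harmonize(iset([rec("rs1", "A", "G")]), [rec("rs1", "A", "C")])


def palindromic_truth(eaf_x, eaf_y_listed, labels_swapped):
    """Independent enumeration oracle for palindromic alignment.

    After label alignment the outcome frequency refers to the exposure's
    labeled effect allele; sides of 0.5 disagreeing means the outcome file
    sits on the other strand, so the orientation toggles once more.
    """
    flipped = labels_swapped
    eaf_y = 1 - eaf_y_listed if labels_swapped else eaf_y_listed
    if (eaf_x < 0.5) != (eaf_y < 0.5):
        flipped = not flipped
    return flipped


@pytest.mark.parametrize("eaf_x,eaf_y", [(0.30, 0.29), (0.30, 0.71),
                                         (0.70, 0.30), (0.70, 0.69)])
@pytest.mark.parametrize("swap", [False, True])
def test_palindromic_inference_matches_truth_table(eaf_x, eaf_y, swap):
    ea, oa = ("T", "A") if swap else ("A", "T")
    h = harmonize_one(rec("rs1", "A", "T", eaf=eaf_x, beta=0.1),
                      rec("rs1", ea, oa, eaf=eaf_y, beta=0.05))
    want_flip = palindromic_truth(eaf_x, eaf_y, swap)
    assert h.flipped == want_flip
    assert h.beta_y == (-0.05 if want_flip else 0.05)


def test_palindromic_ambiguous_eaf_dropped():
    with pytest.raises(InstrumentError):
        harmonize_one(rec("rs1", "A", "T", eaf=0.48, beta=0.1),
                      rec("rs1", "A", "T", eaf=0.47, beta=0.05))


def test_palindromic_drop_policy_removes():
    with pytest.raises(InstrumentError):
        harmonize_one(rec("rs1", "C", "G", eaf=0.2, beta=0.1),
                      rec("rs1", "C", "G", eaf=0.2, beta=0.05),
                      palindromic_policy="drop")


def test_harmonization_involutive_under_strand_complement():
    """Complementing both outcome alleles changes nothing but the labels."""
    exposure = [rec("rs1", "A", "G", beta=0.1), rec("rs2", "C", "A", beta=-0.2),
                rec("rs3", "A", "T", eaf=0.3, beta=0.1)]
    outcome = [rec("rs1", "G", "A", beta=0.05), rec("rs2", "C", "A", beta=0.07),
               rec("rs3", "A", "T", eaf=0.31, beta=0.02)]
    flipped_strand = [
        SummaryRecord(r.variant_id, COMPLEMENT[r.effect_allele],
                      COMPLEMENT[r.other_allele], r.eaf, r.beta, r.se, r.pvalue)
        for r in outcome]
    hs1, _ = harmonize(iset(exposure), outcome)
    hs2, _ = harmonize(iset(exposure), flipped_strand)
    for a, b in zip(hs1, hs2):
        assert (a.variant_id, a.beta_x, a.beta_y) == (b.variant_id, b.beta_x, b.beta_y)


def test_proxy_sign_orients_outcome_without_allele_comparison():
    exposure = iset([rec("rs1", "A", "G", beta=0.1, proxy_of="rs_orig",
                         proxy_sign=-1)])
    # proxy record in the outcome has unrelated alleles
    outcome = [rec("rs1", "C", "T", beta=0.05)]
    hs, _ = harmonize(exposure, outcome)
    assert hs[0].beta_y == -0.05 and hs[0].proxy_of == "rs_orig"
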