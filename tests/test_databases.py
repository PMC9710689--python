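"""Database loading and the annotation join."""

import numpy as np
import pytest

from conftest import make_call, make_dbs
from toscalite.databases import (ClinicalRecord, DatabaseSet, PopulationDB,
                                 PopulationRecord, annotate, load_database,
                                 lookup)
from toscalite.variants import ConfigError, FormatError, VariantKey


def test_population_tsv_load(tmp_path):
    p = tmp_path / "pop.tsv"
    p.write_text("chrom\tpos\tref\talt\taf\n"
                 "1\t100\tA\tG\t0.001\n"
                 "1\t200\tC\tT\t0.02\n"
                 "2\t300\tG\tA\t0.5\n")
    db = load_database(p, kind="population", name="EXAC", format="tsv")
    assert len(db) == 3
    assert db.records[VariantKey("1", 200, "C", "T")].af == pytest.approx(0.02)
    assert db.priority == 1  # ExAC default rank: highest priority


def test_duplicate_indel_spellings_collapse(tmp_path):
    # the same deletion spelled two ways must occupy a single key
    p = tmp_path / "pop.tsv"
    p.write_text("chrom\tpos\tref\talt\taf\n"
                 "1\t100\tCAA\tCA\t0.10\n"
                 "1\t100\tCAAT\tCAT\t0.30\n")
    db = load_database(p, kind="population", name="KG1000", format="tsv")
    assert len(db) == 1
    key = VariantKey("1", 100, "CA", "C")
    assert db.records[key].af == pytest.approx(0.30)  # duplicate rule: max AF


def test_empty_database_file(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    db = load_database(p, kind="population", name="ESP", format="tsv")
    assert len(db) == 0


def test_af_out_of_range_rejected(tmp_path):
    p = tmp_path / "pop.tsv"
    p.write_text("chrom\tpos\tref\talt\taf\n1\t100\tA\tG\t1.5\n")
    with pytest.raises(FormatError, match=r"\[0, 1\]"):
        load_database(p, kind="population", name="EXAC", format="tsv")


def test_unknown_kind_is_config_error(tmp_path):
    p = tmp_path / "x.tsv"
    p.write_text("chrom\tpos\tref\talt\n")
    with pytest.raises(ConfigError, match="kind"):
        load_database(p, kind="frequencies", name="EXAC", format="tsv")


def test_vcf_database_with_info_af_and_common(tmp_path):
    p = tmp_path / "db.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1,length=1000000>\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
        '##INFO=<ID=COMMON,Number=0,Type=Flag,Description="common">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t100\trs1\tA\tG\t.\t.\tAF=0.25;COMMON\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\n")
    db = load_database(p, kind="population", name="DBSNP", format="vcf")
    assert len(db) == 2
    rec = db.records[VariantKey("1", 100, "A", "G")]
    assert rec.af == pytest.approx(0.25) and rec.common_flag is True
    assert db.records[VariantKey("1", 200, "C", "T")].af is None


def test_priorities_must_be_unique():
    pop = {"EXAC": PopulationDB(name="EXAC", priority=1),
           "KG1000": PopulationDB(name="KG1000", priority=1)}
    with pytest.raises(ConfigError, match="unique"):
        DatabaseSet(population=pop)


@pytest.mark.parametrize("terms, benign", [
    ({"benign"}, True),
    ({"likely_benign"}, True),
    ({"benign", "likely_benign"}, True),
    ({"pathogenic"}, False),
    ({"benign", "pathogenic"}, False),        # mixed assertions: not benign
    ({"benign", "conflicting"}, False),
    ({"uncertain_significance"}, False),
])
def test_benign_qualification_is_conservative(terms, benign):
    assert ClinicalRecord(significance=frozenset(terms)).is_benign is benign


# ---------------------------------------------------------------------------
# The annotation join
# ---------------------------------------------------------------------------

def _random_keys(rng, n):
    pos = rng.choice(10**6, size=n, replace=False) + 1
    bases = np.array(list("ACGT"))
    keys = []
    for p in pos:
        ref, alt = rng.choice(bases, size=2, replace=False)
        keys.append(VariantKey("1", int(p), str(ref), str(alt)))
    return keys


def test_annotate_matches_linear_scan_oracle():
    rng = np.random.default_rng(42)
    keys = _random_keys(rng, 2000)
    dbs = make_dbs()  # empty evidence; fill subsets below
    for name, db in dbs.population.items():
        db.records.clear()
        for k in keys[:: rng.integers(2, 6)]:
            db.records[k] = PopulationRecord(af=float(rng.uniform(0, 0.5)))
    for k in keys[:: 3]:
        from toscalite.databases import SomaticRecord
        dbs.somatic.records[k] = SomaticRecord(catalogue_id="COSM1")
    calls = [make_call(key=k) for k in keys]
    bundles = [av.evidence for av in annotate(calls, dbs)]
    for k, b in zip(keys, bundles):
        # brute-force linear scan over every stored record
        for name, db in dbs.population.items():
            expected = None
            for stored_key, rec in db.records.items():
                if stored_key == k:
                    expected = rec
            assert b.population_hits.get(name) == expected
        assert b.somatic_hit == dbs.somatic.records.get(k)
        assert b.clinical_hit is None


def test_annotate_is_a_pure_join():
    # adding a record for one key never changes another key's bundle
    rng = np.random.default_rng(7)
    keys = _random_keys(rng, 200)
    dbs = make_dbs(pop_afs={"EXAC": 0.2}, key=keys[0])
    calls = [make_call(key=k) for k in keys[1:]]
    before = [av.evidence for av in annotate(calls, dbs)]
    dbs.population["EXAC"].records[keys[0]] = PopulationRecord(af=0.4)
    from toscalite.databases import SomaticRecord
    dbs.somatic.records[keys[0]] = SomaticRecord(catalogue_id="COSM9")
    after = [av.evidence for av in annotate(calls, dbs)]
    assert before == after


def test_absent_everywhere_yields_empty_bundles():
    rng = np.random.default_rng(3)
    keys = _random_keys(rng, 1000)
    dbs = make_dbs()
    for db in dbs.population.values():
        db.records.clear()
    bundles = [av.evidence for av in annotate([make_call(key=k) for k in keys], dbs)]
    assert all(not b.population_hits and b.somatic_hit is None
               and b.clinical_hit is None for b in bundles)


def test_call_present_in_population_and_catalogue():
    key = VariantKey("1", 100, "A", "G")
    dbs = make_dbs(pop_afs={"EXAC": 0.02}, cosmic=True, key=key)
    b = lookup(key, dbs)
    assert b.population_hits["EXAC"].af == pytest.approx(0.02)
    assert b.somatic_hit is not None
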