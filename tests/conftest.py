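import pytest

from toscalite.databases import (ClinicalDB, ClinicalRecord, DatabaseSet,
                                 DEFAULT_PRIORITIES, PopulationDB,
                                 PopulationRecord, SomaticCatalogue,
                                 SomaticRecord, Switches)
from toscalite.variants import Thresholds, VariantCall, VariantKey


@pytest.fixture
def thresholds():
    return Thresholds.for_mode("TS")


def make_dbs(pop_afs=None, dbsnp=None, cosmic=False, clinvar=None,
             switches=None, key=None):
    """DatabaseSet with evidence attached to a single key.

    pop_afs: dict name->af for KG1000/ESP/EXAC; dbsnp: None | 'common' |
    'present' | float AF; clinvar: iterable of significance terms.
    """
    key = key or VariantKey("1", 100, "A", "G")
    population = {}
    for name in ("KG1000", "ESP", "EXAC"):
        db = PopulationDB(name=name, priority=DEFAULT_PRIORITIES[name])
        if pop_afs and name in pop_afs and pop_afs[name] is not None:
            db.records[key] = PopulationRecord(af=pop_afs[name])
        population[name] = db
    db = PopulationDB(name="DBSNP", priority=DEFAULT_PRIORITIES["DBSNP"])
    if dbsnp == "common":
        db.records[key] = PopulationRecord(af=None, common_flag=True)
    elif dbsnp == "present":
        db.records[key] = PopulationRecord(af=None, common_flag=False)
    elif isinstance(dbsnp, float):
        db.records[key] = PopulationRecord(af=dbsnp)
    population["DBSNP"] = db
    somatic = SomaticCatalogue()
    if cosmic:
        somatic.records[key] = SomaticRecord(catalogue_id="COSM1")
    clinical = ClinicalDB()
    if clinvar:
        clinical.records[key] = ClinicalRecord(significance=frozenset(clinvar))
    return DatabaseSet(population=population, somatic=somatic,
                       clinical=clinical, switches=switches or Switches())


def make_call(key=None, depth=100, alt=30, vaf=None, filt="PASS",
              consequence="missense_variant"):
    key = key or VariantKey("1", 100, "A", "G")
    if vaf is None and depth > 0:
        vaf = alt / depth
    return VariantCall(key=key, total_depth=depth, alt_depth=alt, vaf=vaf,
                       filter_status=filt, consequence=consequence,
                       sample_id="TUMOR")
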