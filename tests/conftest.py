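import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from irbvigil.cohort import MeddraMap
from irbvigil.ingest import deduplicate_faers, read_faers_quarter, select_target_reports
from irbvigil.model import Corpus, DRUG_COLUMNS, REACTION_COLUMNS, REPORT_COLUMNS
from irbvigil.synthdata import SimConfig, generate_corpus, generate_meddra_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


def make_corpus(reports=(), drugs=(), reactions=(), source="FAERS") -> Corpus:
    """Hand-build a corpus from minimal row dicts (missing fields defaulted)."""
    rep_defaults = {
        "case_id": None, "receipt_date": None, "receipt_precision": "missing",
        "event_date": None, "event_precision": "missing", "sex": "unknown",
        "age_value": np.nan, "age_raw": "", "weight_kg": np.nan, "country": None,
        "reporter": "unknown", "outcomes": frozenset(), "indications": (),
    }
    drug_defaults = {"drug_seq": 1, "role": "PS", "start_date": None,
                     "start_precision": "missing", "end_date": None,
                     "end_precision": "missing"}
    reac_defaults = {"event_date": None, "event_precision": "missing"}
    reps = [{**rep_defaults, "case_id": r.get("report_id"), **r} for r in reports]
    drg = [{**drug_defaults, **d} for d in drugs]
    rcs = [{**reac_defaults, **r} for r in reactions]
    return Corpus(
        reports=pd.DataFrame(reps, columns=REPORT_COLUMNS),
        drugs=pd.DataFrame(drg, columns=DRUG_COLUMNS),
        reactions=pd.DataFrame(rcs, columns=REACTION_COLUMNS),
        source=source,
    )


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("sim")


@pytest.fixture(scope="session")
def injected_config():
    """Study-scale synthetic FAERS set with one strong injected signal
    (relative risk 10, expected count comfortably above 20)."""
    return SimConfig(
        n_reports=4000, seed=101, target_share=0.15, duplicate_rate=0.08,
        injected_signals=(("IRBESARTAN", "pt_005", 10.0),),
    )


@pytest.fixture(scope="session")
def injected_files(sim_dir, injected_config):
    paths, truth = generate_corpus(injected_config, sim_dir / "faers_injected", dialect="faers")
    return paths, truth


@pytest.fixture(scope="session")
def injected_corpus(injected_files):
    paths, _ = injected_files
    return deduplicate_faers(read_faers_quarter(paths))


@pytest.fixture(scope="session")
def injected_target(injected_corpus):
    return select_target_reports(injected_corpus, ["IRBESARTAN"])


@pytest.fixture(scope="session")
def meddra_path(sim_dir):
    return generate_meddra_fixture(200, 27, 101, sim_dir / "meddra.tsv")


@pytest.fixture(scope="session")
def meddra(meddra_path):
    return MeddraMap.from_file(meddra_path)


@pytest.fixture(scope="session")
def injected_scan(injected_corpus, injected_target, meddra):
    from irbvigil.dispro import run_signal_scan

    return run_signal_scan(
        injected_corpus, meddra, set(injected_target.reports["report_id"]), level="pt")
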