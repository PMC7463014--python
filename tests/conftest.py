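import numpy as np
import pandas as pd
import pytest

from teloscore import (
    Cohort,
    DiseaseModel,
    SimulationConfig,
    builtin_panel,
    simulate_case_control,
)


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


def make_cohort(panel, genotypes: dict[str, list[int]], phenotypes: dict[str, dict] | None = None) -> Cohort:
    """Build a small in-memory cohort.

    ``genotypes`` maps subject_id -> effect-allele counts in panel order
    (-1 = missing).  Phenotype fields default to a middle-aged Italian
    control unless overridden per subject.
    """
    ids = list(genotypes)
    defaults = {
        "status": "control",
        "age": 55.0,
        "sex": "female",
        "country": "Italy",
        "subtype": "none",
        "jak2": "unknown",
    }
    rows = []
    for sid in ids:
        row = dict(defaults)
        row.update((phenotypes or {}).get(sid, {}))
        rows.append(row)
    pheno = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    geno = pd.DataFrame(
        np.array([genotypes[sid] for sid in ids], dtype=np.int8),
        index=pheno.index,
        columns=panel.rsids,
    )
    return Cohort(pheno, geno, panel)


@pytest.fixture(scope="session")
def null_cohort():
    """A default-margin cohort with no genotype-disease effect."""
    return simulate_case_control(SimulationConfig(seed=11)).cohort


@pytest.fixture(scope="session")
def effect_cohort():
    """A cohort with the published quintile effects injected."""
    cfg = SimulationConfig(
        seed=17,
        disease_model=DiseaseModel(
            kind="quintile_effects",
            quintile_log_or=tuple(np.log([1.25, 1.65, 1.54, 1.82])),
        ),
    )
    return simulate_case_control(cfg)
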