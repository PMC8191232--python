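import numpy as np
import pandas as pd
import pytest

from solnc import syndata
from solnc.genomic_io import TranscriptRecord


@pytest.fixture(scope="session")
def default_config():
    return syndata.SimulationConfig()


@pytest.fixture(scope="session")
def sim_bundle(default_config):
    """One full synthetic dataset at the default study conditions."""
    cfg = default_config
    sequences, annotation = syndata.generate_genome(cfg)
    records, truth = syndata.generate_transcript_set(sequences, annotation, cfg)
    matrix = syndata.generate_count_matrix(records, truth, cfg)
    mirnas, sequences = syndata.generate_mirna_set(sequences, records, truth, cfg)
    panel = syndata.generate_qpcr_panel(matrix, records, truth, cfg)
    return {
        "config": cfg,
        "sequences": sequences,
        "annotation": annotation,
        "records": records,
        "truth": truth,
        "matrix": matrix,
        "mirnas": mirnas,
        "panel": panel,
    }


def make_dummy_records(n: int) -> list[TranscriptRecord]:
    """Featureless transcript records for count-simulation tests."""
    return [
        TranscriptRecord(
            id=f"T{i:05d}", chrom="chr01", strand="+", exons=((0, 100),),
            sequence="A" * 100,
        )
        for i in range(n)
    ]


def dummy_truth(records) -> syndata.TruthTable:
    return syndata.TruthTable(
        transcripts=pd.DataFrame(
            {"true_class": "mRNA", "true_coding": True}, index=[r.id for r in records]
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
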