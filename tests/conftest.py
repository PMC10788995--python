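import numpy as np
import pandas as pd
import pytest

from lncpairsig import ClinicalTable, ExpressionMatrix, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized simulated cohort shared by read-only tests."""
    return simulate_cohort(
        n_tumor=200,
        n_normal=40,
        n_lnc=60,
        n_coding=60,
        n_geneset=20,
        n_linked_lnc=20,
        seed=2,
    )


@pytest.fixture
def expr_from_frame():
    """Build an ExpressionMatrix from a plain values DataFrame."""

    def _make(values: pd.DataFrame, normal=(), biotype="lncRNA"):
        groups = pd.Series(
            ["normal" if s in set(normal) else "tumor" for s in values.columns],
            index=values.columns,
        )
        return ExpressionMatrix(values, pd.Series(biotype, index=values.index), groups)

    return _make


@pytest.fixture
def surv_from_arrays():
    """Build a minimal ClinicalTable from time/event arrays."""

    def _make(time, event, **extra):
        n = len(time)
        ids = [f"S{i + 1:03d}" for i in range(n)]
        data = {
            "os_time": np.asarray(time, dtype=float),
            "os_event": np.asarray(event, dtype=int),
            "age": extra.pop("age", np.full(n, 60)),
            "sex": extra.pop("sex", ["male"] * n),
            "grade": extra.pop("grade", ["G2"] * n),
            "stage": extra.pop("stage", ["II"] * n),
        }
        data.update(extra)
        return ClinicalTable(pd.DataFrame(data, index=pd.Index(ids, name="sample_id")))

    return _make


TINY_GTF = """\
chr1\thavana\tgene\t100\t2000\t.\t+\t.\tgene_id "G1"; gene_name "G1"; gene_biotype "protein_coding";
chr1\thavana\texon\t100\t500\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\thavana\tgene\t3000\t5000\t.\t-\t.\tgene_id "G2"; gene_name "G2"; gene_biotype "lncRNA";
chr2\thavana\tgene\t100\t900\t.\t+\t.\tgene_id "ENSG00000100001"; gene_type "antisense";
"""


@pytest.fixture
def tiny_gtf(tmp_path):
    path = tmp_path / "tiny.gtf"
    path.write_text(TINY_GTF)
    return path
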