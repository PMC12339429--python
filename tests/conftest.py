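import numpy as np
import pytest

from pvmr.mr import HarmonizedSet, SnpAssociation
from pvmr.reports import ReportRecord, ReportSet

DATA_DIR = __import__("pathlib").Path(__file__).parent / "data"


def make_record(
    report_id="R1",
    drugs=("somatropin",),
    pts=((10061019, "brain neoplasm"),),
    **kwargs,
):
    return ReportRecord(
        report_id=report_id,
        drugs=frozenset(drugs),
        pts=frozenset(pts),
        **kwargs,
    )


def make_report_set(cells):
    """Build a ReportSet from (has_drug, has_event, n) triples."""
    records = []
    i = 0
    for has_drug, has_event, n in cells:
        for _ in range(n):
            drugs = ("somatropin",) if has_drug else ("ibuprofen",)
            pts = (
                ((10061019, "brain neoplasm"),)
                if has_event
                else ((10000001, "decoy event 1"),)
            )
            records.append(make_record(report_id=f"R{i}", drugs=drugs, pts=pts))
            i += 1
    return ReportSet(records, provenance="test")


def make_harmonized(beta_exp, beta_out, se_out, se_exp=None, ids=None):
    beta_exp = np.asarray(beta_exp, float)
    k = len(beta_exp)
    se_exp = np.full(k, 0.05) if se_exp is None else np.asarray(se_exp, float)
    return HarmonizedSet(
        ids or [f"rs{i}" for i in range(k)],
        beta_exp,
        se_exp,
        np.asarray(beta_out, float),
        np.asarray(se_out, float),
    )


def make_snp(snp_id="rs1", chrom="1", pos=1_000_000, ea="A", oa="G", eaf=0.3,
             beta=0.2, se=0.05, p=1e-7, n=3301):
    return SnpAssociation(snp_id, chrom, pos, ea, oa, eaf, beta, se, p, n)


@pytest.fixture
def instruments_path():
    return DATA_DIR / "somatropin_instruments.tsv"
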