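import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ratedecay import Dataset, RateEstimate

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    rate=1e-8,
    calibration_time=1e6,
    marker_class="coding",
    marker_name="cytochrome b",
    taxon_group="mammals",
    species="Testus testus",
    study_id="study-1",
    calibration_type="fossil_biogeographic",
):
    return RateEstimate(
        rate=rate,
        calibration_time=calibration_time,
        marker_class=marker_class,
        marker_name=marker_name,
        taxon_group=taxon_group,
        species=species,
        study_id=study_id,
        calibration_type=calibration_type,
    )


def make_dataset(*records):
    return Dataset(records=list(records))


TINY_TSV = """rate\tcalibration_time\tmarker_class\tmarker_name\ttaxon_group\tspecies\tstudy_id\tcalibration_type
1.78E-10\t26000\tcoding\tcytochrome b; tRNA\tmammals\tMammuthus primigenius\ts1\tancient_dna
2.31E-6\t6000\tnoncoding\tcontrol region\tbirds\tPygoscelis adeliae\ts2\tancient_dna
4.5e-8\t6\tnoncoding\tcontrol region\tbirds\tPygoscelis adeliae\ts3\tpedigree
1.2e-9\t400000000\tcoding\tCOI\tinsects\tBacillus rossius\ts4\tfossil_biogeographic
3.3e-9\t6500000\tcoding\tcytochrome b\tmammals\tHomo sapiens\ts5\tfossil_biogeographic
"""


@pytest.fixture
def tiny_table(tmp_path):
    path = tmp_path / "rates.tsv"
    path.write_text(TINY_TSV)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20150305)
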