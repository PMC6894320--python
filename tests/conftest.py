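import numpy as np
import pytest

from repfp import default_study_specs, generate_study


AIRR_HEADER = [
    "sequence_id", "v_call", "j_call", "junction_aa",
    "v_support", "j_support", "productive", "vj_in_frame", "stop_codon",
]


def write_airr(path, rows, header=AIRR_HEADER):
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(row.get(col, "")) for col in header))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def airr_file(tmp_path):
    """Two clean rearrangement rows for one donor."""
    rows = [
        dict(sequence_id="r1", v_call="IGHV1-2*02", j_call="IGHJ4*01",
             junction_aa="CARWGGDYW", v_support=1e-30, j_support=1e-30,
             productive="T", vj_in_frame="T", stop_codon="F"),
        dict(sequence_id="r2", v_call="IGHV3-23*01", j_call="IGHJ6*02",
             junction_aa="CAKYSSGWYFDYW", v_support=1e-12, j_support=1e-9,
             productive="T", vj_in_frame="T", stop_codon="F"),
    ]
    return write_airr(tmp_path / "d1.airr.tsv", rows)


@pytest.fixture(scope="session")
def small_study():
    """3+5-donor synthetic study at reduced repertoire size (fast)."""
    spec_a, spec_b = default_study_specs(
        effect_size=1.0, clonotypes_per_donor=5000
    )
    return generate_study(spec_a, spec_b, seed=11)
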