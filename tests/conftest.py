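"""Shared fixtures: hand-built toy embryos and small simulated cohorts."""

import textwrap

import pytest

from cleavekit import build_lineage, embryos_from_frame, parse_division_table
import pandas as pd


T1_CSV = textwrap.dedent(
    """\
    embryo_id,group,treatment,cell_id,parent_id,birth_hpa,end_hpa,fate,aberrancy,cytokinesis_onset_hpa,blastocyst,esc,fetus
    T1,ICSI,none,1,,0.0,20.0,divided,none,19.5,1,NA,NA
    T1,ICSI,none,1.1,1,20.0,38.0,divided,none,,1,NA,NA
    T1,ICSI,none,1.2,1,20.0,39.0,divided,none,,1,NA,NA
    T1,ICSI,none,1.1.1,1.1,38.0,50.0,divided,none,,1,NA,NA
    T1,ICSI,none,1.1.2,1.1,38.0,50.5,divided,none,,1,NA,NA
    T1,ICSI,none,1.2.1,1.2,39.0,51.0,divided,none,,1,NA,NA
    T1,ICSI,none,1.2.2,1.2,39.0,53.0,divided,none,,1,NA,NA
    """
)

T2_CSV = textwrap.dedent(
    """\
    embryo_id,group,treatment,cell_id,parent_id,birth_hpa,end_hpa,fate,aberrancy,cytokinesis_onset_hpa,blastocyst,esc,fetus
    T2,NT,none,1,,0.0,22.0,divided,none,,0,NA,NA
    T2,NT,none,1.1,1,22.0,96.0,censored,none,,0,NA,NA
    T2,NT,none,1.2,1,22.0,96.0,censored,none,,0,NA,NA
    """
)


@pytest.fixture
def t1_path(tmp_path):
    path = tmp_path / "t1.csv"
    path.write_text(T1_CSV)
    return path


@pytest.fixture
def t1_embryo(t1_path):
    (embryo,) = parse_division_table(t1_path)
    return embryo


@pytest.fixture
def t1_tree(t1_embryo):
    return build_lineage(t1_embryo)


@pytest.fixture
def t2_tree(tmp_path):
    path = tmp_path / "t2.csv"
    path.write_text(T2_CSV)
    (embryo,) = parse_division_table(path)
    return build_lineage(embryo)


def make_embryo_frame(rows):
    """Build a division-event frame from (cell_id, parent, birth, end, fate)
    tuples for a single synthetic embryo."""
    recs = []
    for cell_id, parent, birth, end, fate in rows:
        recs.append(
            {
                "embryo_id": "E1",
                "group": "ICSI",
                "cell_id": cell_id,
                "parent_id": parent,
                "birth_hpa": birth,
                "end_hpa": end,
                "fate": fate,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def icsi_cohort_500():
    """Medium ICSI cohort shared by the slower statistics tests."""
    from cleavekit import features_frame, preset, simulate_embryos

    embryos = simulate_embryos(preset("ICSI-default", n_embryos=500, seed=7))
    trees = [build_lineage(e) for e in embryos]
    return embryos, trees, features_frame(embryos)
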