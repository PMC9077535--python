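import numpy as np
import pandas as pd
import pytest

from omicforest import SynthConfig, assemble, simulate
from omicforest.simulate import MultiomicsBundle


@pytest.fixture(scope="session")
def default_config():
    """The default synthetic study conditions (200 proteins x 20 samples)."""
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def default_sim(default_config):
    return simulate(default_config)


@pytest.fixture(scope="session")
def default_design(default_sim):
    bundle, _ = default_sim
    return assemble(bundle)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SynthConfig(n_proteins=40, n_samples=9, seed=3))


@pytest.fixture(scope="session")
def small_design(small_sim):
    bundle, _ = small_sim
    return assemble(bundle)


def build_toy_bundle() -> MultiomicsBundle:
    """Two proteins with hand-picked linkage so every feature is checkable.

    P0001 maps to transcripts T1 (+) and T2 (-); its miRNA set is
    {M1 (score 85), M2 (60), M3 (92)} with stringent subset {M1, M3}.
    circRNA C1 reaches it through links with 8 and 10 binding sites; C2's
    single link has exactly 7 sites and must stay invisible.  P0002 has a
    single transcript T3 targeted by M2 at exactly the stringent boundary
    score of 80.
    """
    samples = ["SA", "SB"]
    sidx = pd.Index(samples, name="sample_id")

    transcript_expr = pd.DataFrame(
        {"SA": [10.0, 30.0, 7.0], "SB": [1.0, 3.0, 7.0]},
        index=pd.Index(["T1", "T2", "T3"], name="transcript_id"))
    mirna_expr = pd.DataFrame(
        {"SA": [100.0, 50.0, 20.0], "SB": [10.0, 5.0, 2.0]},
        index=pd.Index(["M1", "M2", "M3"], name="mirna_id"))
    circ_expr = pd.DataFrame(
        {"SA": [12.0, 8.0], "SB": [6.0, 4.0]},
        index=pd.Index(["C1", "C2"], name="circ_id"))
    protein_expr = pd.DataFrame(
        {"SA": [1024.0, 2.0], "SB": [np.nan, 4.0]},
        index=pd.Index(["P0001", "P0002"], name="protein_id"))

    protein_transcript_map = pd.DataFrame(
        [("P0001", "T1"), ("P0001", "T2"), ("P0002", "T3")],
        columns=["protein_id", "transcript_id"])
    mti_table = pd.DataFrame(
        [("M1", "T1", 85.0), ("M2", "T1", 60.0), ("M3", "T2", 92.0),
         ("M2", "T3", 80.0)],
        columns=["mirna_id", "transcript_id", "score"])
    circ_site_table = pd.DataFrame(
        [("C1", "M1", 8), ("C2", "M1", 7), ("C1", "M3", 10)],
        columns=["circ_id", "mirna_id", "n_sites"])

    from omicforest.simulate import AA_ORDER
    annot = pd.DataFrame(index=pd.Index(["P0001", "P0002"], name="protein_id"))
    annot["Length"] = [100, 50]
    annot["Mass"] = [11000.0, 5500.0]
    counts = {a: [0, 0] for a in AA_ORDER}
    counts["A"] = [12, 10]
    counts["L"] = [88, 0]
    counts["G"] = [0, 40]
    for a in AA_ORDER:
        annot[f"Aa_{a}"] = counts[a]
    annot["Organism"] = "Human"
    annot["Gene.encoded.by"] = ["Nucleus", "Mitochondrion"]
    annot["Version..sequence."] = [1, 2]
    for m in range(1, 10):
        annot[f"stability_{m}_rep1"] = float(m)
        annot[f"stability_{m}_rep2"] = float(m + 2)

    transcript_annot = pd.DataFrame(
        {
            "strand": ["+", "-", "+"],
            "transcript_length": [1000, 2000, 1000],
            "percentage_gene_gc_content": [46.0, 50.0, 40.0],
            "cds_length": [600, 1500, 600],
        },
        index=pd.Index(["T1", "T2", "T3"], name="transcript_id"))

    go_annot = pd.DataFrame([("P0001", "GO:0000001"), ("P0002", "GO:0000001")],
                            columns=["protein_id", "go_term"])
    seq_depth = pd.Series([1.0e6, 2.0e6], index=sidx, name="seq_depth")
    sample_meta = pd.DataFrame(
        {"timepoint": ["T1", "T1"], "replicate": ["R1", "R2"],
         "treatment": ["UNTR", "UNTR"]}, index=sidx)

    bundle = MultiomicsBundle(
        transcript_expr=transcript_expr, mirna_expr=mirna_expr,
        circ_expr=circ_expr, protein_expr=protein_expr,
        protein_transcript_map=protein_transcript_map, mti_table=mti_table,
        circ_site_table=circ_site_table, protein_annot=annot,
        transcript_annot=transcript_annot, go_annot=go_annot,
        seq_depth=seq_depth, sample_meta=sample_meta)
    bundle.validate()
    return bundle


@pytest.fixture()
def toy_bundle():
    return build_toy_bundle()
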