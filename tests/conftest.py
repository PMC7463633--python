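import numpy as np
import pandas as pd
import pytest

from fusemet.feature_io import AbundanceMatrix


def make_matrix(values, scale="raw", cell_lines=None, treatments=None,
                replicates=None, ion_modes=None, mdm2=None, factors=None,
                feature_meta=None):
    """Build an AbundanceMatrix from a {feature_id: [values]} dict.

    Sample metadata defaults to one cell line per pair of samples, all
    untreated, alternating replicates — enough structure for the filters.
    """
    values = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    n = len(next(iter(values.values())))
    sample_ids = [f"s{i + 1}" for i in range(n)]
    if cell_lines is None:
        cell_lines = [f"CL{i // 2 + 1}" for i in range(n)]
    if mdm2 is None:
        uniq = sorted(set(cell_lines), key=cell_lines.index)
        half = {cl: ("high" if k < (len(uniq) + 1) // 2 else "low")
                for k, cl in enumerate(uniq)}
        mdm2 = [half[cl] for cl in cell_lines]
    if treatments is None:
        treatments = ["untreated"] * n
    if replicates is None:
        seen = {}
        replicates = []
        for cl, tr in zip(cell_lines, treatments):
            seen[(cl, tr)] = seen.get((cl, tr), 0) + 1
            replicates.append(seen[(cl, tr)])
    samples = pd.DataFrame(
        {
            "cell_line": cell_lines,
            "mdm2_status": mdm2,
            "treatment": treatments,
            "replicate": replicates,
            "ion_mode": ion_modes if ion_modes is not None else "none",
            "normalization_factor": factors if factors is not None else 1.0,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=sample_ids).T
    vals.index.name = "feature_id"
    features = pd.DataFrame(
        {
            "display_name": vals.index,
            "superclass": None,
            "adduct": None,
            "ion_mode": "none",
            "ms_level_identified": None,
        },
        index=vals.index,
    )
    if feature_meta:
        for fid, meta in feature_meta.items():
            for col, val in meta.items():
                features.loc[fid, col] = val
    return AbundanceMatrix(values=vals, missing_mask=vals.isna(),
                           features=features, samples=samples, scale=scale)


@pytest.fixture
def toy_pathway_db():
    from fusemet.network_enrichment import PathwayDatabase

    return PathwayDatabase(
        pathways={
            "P1": {"m1", "m2", "m3"},
            "P2": {"m2", "m3", "m4"},
            "P3": {"m5", "m6", "m7"},
        },
        names={"P1": "alpha", "P2": "beta", "P3": "gamma"},
    )
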