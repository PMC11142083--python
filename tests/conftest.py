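import numpy as np
import pytest

from famscan import (
    SimConfig,
    kinship_matrix,
    simulate_dataset,
    derive_adjusted_trait,
    ibd_matrix_from_state,
)
from famscan.linkage import IBDMatrix


def subset_ibd(mat: IBDMatrix, ids) -> IBDMatrix:
    return IBDMatrix(chrom=mat.chrom, pos=mat.pos, ids=list(ids), values=mat.reindex(ids))


@pytest.fixture(scope="session")
def qtl_scenario():
    """Moderate-size simulated study with a QTL: everything aligned to the
    analysis id order."""
    cfg = SimConfig(n_families=120, seed=42)
    ped, geno, state, pheno = simulate_dataset(cfg)
    kin = kinship_matrix(ped)
    trait = derive_adjusted_trait(pheno, ["age", "sex", "center"])
    ids = list(trait.table.index)
    kin_sub = kin.subset(ids)
    y = trait.table["transformed"].reindex(ids).to_numpy()
    X = np.ones((len(ids), 1))
    gi = {i: k for k, i in enumerate(geno.ids)}
    order = [gi[i] for i in ids]
    ibd = [
        subset_ibd(ibd_matrix_from_state(state, k), ids)
        for k in range(len(state.loci))
    ]
    return {
        "cfg": cfg,
        "ped": ped,
        "geno": geno,
        "state": state,
        "pheno": pheno,
        "kin": kin_sub,
        "ids": ids,
        "y": y,
        "X": X,
        "ibd": ibd,
        "qtl_dosage": geno.dosages[order, :][:, int(state.loci.index[state.loci["variant_id"] == "qtl"][0])],
    }
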