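"""Per-family LOD decomposition, linkage-enriched family selection and
percent-of-linkage accounting for the causal variant.

The total LOD at the peak factorises over families; families with
PEDLOD > 0.1 (or PEDLOD per phenotyped member > 0.01) are "potentially
linked", and the smallest high-LOD set cumulating to LOD 9 is "top linked".
Conditioning the scan on the causal dosage shows how much of the peak the
variant explains.
"""

import numpy as np

from famscan import (
    SimConfig, simulate_dataset, kinship_matrix, derive_adjusted_trait,
    lod_scan, family_lods, select_linked_families, linkage_accounted,
)
from famscan.simulate import ibd_matrix_from_state
from famscan.linkage import IBDMatrix

cfg = SimConfig(n_families=200, seed=7)
ped, geno, state, pheno = simulate_dataset(cfg)
trait = derive_adjusted_trait(pheno, ["age", "sex", "center"])
ids = list(trait.table.index)
kin = kinship_matrix(ped).subset(ids)
y = trait.table["transformed"].to_numpy()
X = np.ones((len(ids), 1))

mat = ibd_matrix_from_state(state, "qtl")
mat = IBDMatrix(mat.chrom, mat.pos, ids, mat.reindex(ids))
scan = lod_scan(y, X, kin, [mat])
print(f"LOD at the QTL locus: {scan.peak_lod:.2f}")

fams = family_lods(y, X, kin, mat, scan)
print(f"sum of per-family contributions: {sum(f.pedlod for f in fams):.6f} (equals the LOD)")
sel = select_linked_families(fams)
print(f"{len(sel['potentially_linked'])} potentially linked families, "
      f"{len(sel['top_linked'])} top linked")

gi = {i: k for k, i in enumerate(geno.ids)}
g = geno.dosage_of("qtl")[[gi[i] for i in ids]]
acct = linkage_accounted(y, X, kin, mat, g)
print(f"conditioning on the causal dosage: LOD {acct['lod0']:.2f} -> "
      f"{acct['lod_conditioned']:.2f}, accounting for {acct['percent']:.1f}% of linkage")
# Near-100% accounting means the tested variant tags essentially all of the
# locus-specific variance; an unrelated variant would leave the LOD intact.
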