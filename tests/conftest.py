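import numpy as np
import pandas as pd
import pytest

import genepart as gp


def make_genotypes(dosages, chroms=None, positions=None, ids=None):
    """Small GenotypeMatrix from a literal dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"M{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else [100 * (j + 1) for j in range(m)],
        }
    )
    iids = ids if ids is not None else [f"I{i}" for i in range(n)]
    return gp.GenotypeMatrix(dosages, iids, markers)


def gene_target(index, n_markers, frac, rng):
    """Accumulate random mapped genes until their marker union reaches a
    fraction of the panel (a designated enriched 'pathway')."""
    genes = index.mapped_genes()
    order = rng.permutation(len(genes))
    seen = np.zeros(n_markers, dtype=bool)
    picked = []
    for gi in order:
        g = genes[gi]
        picked.append(g)
        seen[index.gene_markers[g]] = True
        if seen.sum() >= frac * n_markers:
            break
    return gp.FeatureSet("target", np.nonzero(seen)[0], genes=tuple(picked))


@pytest.fixture(scope="session")
def small_dataset():
    """One mid-size synthetic dataset shared by read-mostly tests:
    120 individuals x 1000 markers, genes covering ~40 % of markers."""
    scn = gp.SimulationScenario(n_individuals=120, n_markers=1000, n_chromosomes=4, seed=17)
    geno = gp.simulate_genotypes(scn)
    genes, pmap, focal = gp.simulate_annotation(scn, geno)
    index = gp.map_markers_to_genes(geno, genes)
    pheno, truth = gp.simulate_phenotypes(scn, geno)
    return dict(scn=scn, geno=geno, genes=genes, pmap=pmap, focal=focal,
                index=index, pheno=pheno, truth=truth)
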