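import numpy as np
import pandas as pd
import pytest

from gcaqtl import simdata
from gcaqtl.genmap import GeneticMap, GenotypeMatrix


@pytest.fixture
def small_map() -> GeneticMap:
    """Two chromosomes, 6 markers, uneven spacing."""
    return GeneticMap(
        marker_ids=np.array(["m1", "m2", "m3", "m4", "m5", "m6"], dtype=object),
        chrom=np.array([1, 1, 1, 2, 2, 2], dtype=object),
        cm=np.array([0.0, 10.0, 30.0, 0.0, 5.0, 25.0]),
        mb=np.array([1.0, 12.0, 33.0, 1.0, 7.0, 28.0]),
    )


@pytest.fixture
def small_genotypes(small_map) -> GenotypeMatrix:
    codes = np.array(
        [
            [0, 0, 0, 2, 2, 2],
            [2, 2, 2, 0, 0, 0],
            [0, -1, 2, 2, 1, 0],
            [2, 0, 0, 0, 0, 2],
            [0, 0, 2, 2, 2, 2],
        ],
        dtype=np.int8,
    )
    lines = np.array([f"L{i}" for i in range(1, 6)], dtype=object)
    return GenotypeMatrix(lines, small_map.marker_ids, codes)


@pytest.fixture(scope="session")
def sim_bundle():
    """One mid-size simulated dataset shared across estimation tests."""
    gmap = simdata.make_genetic_map(3, 20, 120.0)
    geno = simdata.simulate_ril_genomes(gmap, 120, 11, seed=11, method="markov")
    design = simdata.build_ncii_design(list(geno.line_ids), ["T1", "T2"])
    env = simdata.EnvSpec()
    arch = simdata.TraitArchitecture(
        trait="kt",
        mean=10.0,
        tester_effects={"T1": 1.0, "T2": -1.0},
        qtl=[
            simdata.QTLEffect(
                chrom=1, pos_cm=60.0, add_perse=0.5, add_tester={"T1": 0.5, "T2": 0.5}
            )
        ],
        env_sd=0.5,
        gxe_sd=0.2,
        block_sd=0.1,
        resid_sd=0.6,
    )
    sim = simdata.simulate_phenotypes(geno, gmap, arch, design, env, seed=12)
    return {
        "gmap": gmap,
        "geno": geno,
        "design": design,
        "env": env,
        "arch": arch,
        "sim": sim,
    }


def balanced_pheno(values_by_entry_env_rep, trait="t", population="RIL") -> pd.DataFrame:
    """Build a long phenotype table from nested {entry: {(loc, yr): [reps]}}."""
    rows = []
    for entry, envs in values_by_entry_env_rep.items():
        for (loc, yr), reps in envs.items():
            for r, v in enumerate(reps, start=1):
                rows.append((entry, population, loc, yr, r, trait, float(v)))
    return pd.DataFrame(
        rows, columns=["entry", "population", "location", "year", "rep", "trait", "value"]
    )
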