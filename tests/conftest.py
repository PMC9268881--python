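import numpy as np
import pandas as pd
import pytest

from cnvburden.synthetic import CohortConfig, simulate_cohort
from cnvburden.types import IntensityPanel, MarkerMap


SMALL_CONFIG = dict(
    n_families=12,
    n_population_controls=40,
    n_chromosomes=3,
    n_markers_per_chrom=800,
    seed=7,
)


@pytest.fixture(scope="session")
def small_bundle():
    """One modest cohort shared by read-only tests."""
    return simulate_cohort(CohortConfig(**SMALL_CONFIG))


CNV_FREE_CONFIG = dict(
    SMALL_CONFIG,
    p_family_cnv=0.0,
    background_cnv_rate=0.0,
    de_novo_rate=0.0,
    n_common_loci=0,
)


@pytest.fixture(scope="session")
def cnv_free_bundle():
    """Cohort with batch effects and noise but no CNVs at all: the clean
    benchmark for batch correction and caller false-positive rates."""
    return simulate_cohort(CohortConfig(**CNV_FREE_CONFIG))


@pytest.fixture()
def flat_panel():
    """Noise-free copy-neutral panel: LRR 0 everywhere, BAF from genotype."""

    def _make(n_markers=200, n_samples=2, chrom_names=("1",), seed=11):
        rng = np.random.default_rng(seed)
        rows = []
        for chrom in chrom_names:
            pos = np.cumsum(rng.integers(2000, 4000, size=n_markers)) + 1000
            for i in range(n_markers):
                rows.append((f"rs{chrom}_{i}", chrom, int(pos[i]), 0.5))
        marker_map = MarkerMap(
            pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "pfb"])
        )
        m = len(marker_map)
        ids = [f"S{i}" for i in range(n_samples)]
        genotype = rng.binomial(2, 0.5, size=(n_samples, m))
        lrr = pd.DataFrame(np.zeros((n_samples, m)), index=ids, columns=marker_map.marker_ids)
        baf = pd.DataFrame(genotype / 2.0, index=ids, columns=marker_map.marker_ids)
        return IntensityPanel(marker_map, lrr, baf)

    return _make
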