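import numpy as np
import pandas as pd
import pytest

from chromlink import Genome, IntervalSet, PipelineConfig, SimConfig, generate
from chromlink import GroundTruthManifest
from chromlink.pipeline import run as run_pipeline


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return Genome({"chr1": 1_000_000, "chr2": 800_000, "chr3": 500_000})


def random_intervals(rng: np.random.Generator, genome: Genome, n: int,
                     max_len: int = 5_000, scores: bool = False) -> IntervalSet:
    chroms = rng.choice(genome.names, size=n)
    lengths = np.array([genome[c] for c in chroms])
    starts = (rng.random(n) * (lengths - max_len - 1)).astype(np.int64)
    ends = starts + rng.integers(1, max_len, size=n)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    df["name"] = [f"iv{i}" for i in range(n)]
    if scores:
        df["score"] = rng.uniform(0, 8, size=n).round(3)
    return IntervalSet(df, genome)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Default-condition synthetic dataset plus its full pipeline run.

    Session-scoped: generation plus the pipeline takes a couple of
    seconds and many tests only read the results.
    """
    root = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(seed=20240917)
    paths, manifest = generate(cfg, root / "data")
    outdir = root / "out"
    summary = run_pipeline(PipelineConfig.from_simulated(paths, outdir))
    return {
        "cfg": cfg,
        "paths": paths,
        "manifest": manifest,
        "outdir": outdir,
        "summary": summary,
    }
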