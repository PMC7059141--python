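import numpy as np
import pytest

from subteloscreen import synthetic_data as sd
from subteloscreen.candidate_screen import run_screen
from subteloscreen.its_scanner import INTERSTITIAL, classify_arrays, scan_arrays
from subteloscreen.peak_differential import compare_conditions, label_modulated

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(BASES, size=length, p=probs).tobytes().decode("ascii")


def plant_runs(rng: np.random.Generator, seq: str, motif: str = "TTAGGG",
               n_runs: int = 5, max_units: int = 12, degenerate: bool = False) -> str:
    """Paste telomere-like runs (possibly with substitutions) into a string."""
    from subteloscreen.its_scanner import revcomp

    chars = list(seq)
    for _ in range(n_runs):
        units = int(rng.integers(2, max_units + 1))
        unit = motif if rng.random() < 0.5 else revcomp(motif)
        run = list(unit * units)
        if degenerate and units > 1 and rng.random() < 0.7:
            for _ in range(int(rng.integers(1, units))):
                pos = int(rng.integers(6, len(run)))
                run[pos] = "ACGT"[int(rng.integers(4))]
        if len(run) >= len(chars):
            continue
        start = int(rng.integers(0, len(chars) - len(run)))
        chars[start : start + len(run)] = run
    return "".join(chars)


@pytest.fixture(scope="session")
def bundle():
    """The default planted-truth screen fixture (seed 0)."""
    return sd.make_screen_fixture(seed=0)


@pytest.fixture(scope="session")
def screen_result(bundle):
    """Full pipeline run on the fixture: scan -> classify -> diff -> screen."""
    arrays = []
    for seq in bundle.assembly:
        arrays.extend(scan_arrays(seq))
    arrays = classify_arrays(arrays, bundle.assembly.chrom_sizes)
    its = [a for a in arrays if a.array_class == INTERSTITIAL]
    diff = compare_conditions(bundle.peaks_a, bundle.peaks_b)
    lost, gained = label_modulated(diff, "A_is_control")
    report = run_screen(lost, gained, its, bundle.genes, window=bundle.window)
    return {"arrays": arrays, "its": its, "diff": diff, "lost": lost,
            "gained": gained, "report": report}
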