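"""Synthetic benchmark data with controlled ground truth.

The generator emulates the statistical structure the pipeline is built to
detect, without mimicking real human UTR composition:

* 147-nt target windows with a centered 7-nt seed-match site; a configurable
  fraction are "structured": a stem arm spanning the site is mirrored
  (reverse complement) downstream so the site is locked in a helix and the
  window's opening energy is strictly negative under the internal folder;
* a 9-mer motif planted outside the site/stem region with a higher
  probability in structured (low-accessibility) windows than elsewhere,
  giving a configurable enrichment odds;
* expression panels where a designated target subset Φ is repressed only in
  samples where both the miRNA and an RBP proxy gene are highly expressed —
  joint-high and joint-low sample blocks plus mixed (one-regulator-high)
  samples, so single-regulator sample orderings genuinely underperform the
  joint ordering.

All randomness flows from one root seed through named substreams, so window
generation, motif placement, and expression panels can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import reverse_complement, write_fasta, write_site_table
from .sequence_sites import MirnaFamily, SeedSite, TargetWindow

logger = logging.getLogger(__name__)

#: substream tags (mixed into the root seed)
_STREAM_WINDOWS, _STREAM_MOTIF, _STREAM_EXPRESSION = 0, 1, 2

DEFAULT_FAMILY = MirnaFamily(family_name="mir-syn", seed="GAGGUAG")

WINDOW_LENGTH = 147
SITE_START = 70  # centered 7-nt site at [70, 77)
SITE_END = 77


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the stated synthetic world (defaults are the benchmark)."""

    n_windows: int = 200
    gc_background: float = 0.5
    structured_fraction: float = 0.5
    stem_length: int = 21
    motif: str = "UGUAUAUAU"
    motif_prob_top: float = 0.9
    motif_prob_rest: float = 0.05
    n_samples: int = 40
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 1
    #: restrict background letters ("AC" gives a provably pairing-free
    #: background so unstructured windows have exactly zero opening energy;
    #: the realistic default ACGU background folds residually by chance)
    background_alphabet: str = "ACGU"

    def __post_init__(self) -> None:
        for p in (self.motif_prob_top, self.motif_prob_rest,
                  self.structured_fraction, self.gc_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/fractions must be in [0, 1]")
        if self.n_windows < 20:
            raise ValueError("n_windows must be >= 20")
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _random_rna(
    rng: np.random.Generator, length: int, gc: float, alphabet: str = "ACGU"
) -> list[str]:
    letters = sorted(set(alphabet))
    if set(letters) - set("ACGU") or not letters:
        raise ValueError("background_alphabet must be a non-empty subset of ACGU")
    strong = [c for c in letters if c in "GC"]
    weak = [c for c in letters if c in "AU"]
    if not strong or not weak:
        probs = [1.0 / len(letters)] * len(letters)
    else:
        probs = [
            (gc / len(strong)) if c in "GC" else ((1 - gc) / len(weak))
            for c in letters
        ]
    return list(rng.choice(letters, size=length, p=probs))


def _stem_arms(spec: SyntheticSpec) -> tuple[range, range]:
    """Left arm centered on the site; right arm mirrored downstream."""
    center = (SITE_START + SITE_END - 1) // 2
    left_start = center - spec.stem_length // 2
    left = range(left_start, left_start + spec.stem_length)
    right_start = left.stop + 10  # >= min-loop separation
    right = range(right_start, right_start + spec.stem_length)
    if right.stop > WINDOW_LENGTH:
        raise ValueError("stem_length too large for the window")
    return left, right


def _allowed_motif_starts(spec: SyntheticSpec) -> list[int]:
    left, right = _stem_arms(spec)
    k = len(spec.motif)
    return [
        s
        for s in range(WINDOW_LENGTH - k + 1)
        if s + k <= left.start or s >= right.stop
    ]


def generate_windows(
    spec: SyntheticSpec, family: MirnaFamily = DEFAULT_FAMILY
) -> tuple[list[TargetWindow], pd.DataFrame]:
    """Generate windows plus a ground-truth table (structure/planting flags).

    Structured windows get a perfect stem over the site; the motif is planted
    with probability ``motif_prob_top`` in structured windows and
    ``motif_prob_rest`` otherwise, always clear of the site and stem.  The
    output is fully reproducible from the spec's seed.
    """
    rng_win = _rng(spec, _STREAM_WINDOWS)
    rng_motif = _rng(spec, _STREAM_MOTIF)
    site_seq = reverse_complement(family.seed)
    n_structured = int(round(spec.structured_fraction * spec.n_windows))
    left, right = _stem_arms(spec)
    allowed = _allowed_motif_starts(spec)
    motif = spec.motif
    k = len(motif)

    # structured windows are scattered over the index range so ground truth
    # never correlates with gene-id order (deterministic tie-breaks downstream
    # would otherwise be confounded with the planted labels)
    structured_idx = set(
        int(i) for i in rng_win.permutation(spec.n_windows)[:n_structured]
    )

    windows: list[TargetWindow] = []
    truth_rows = []
    for idx in range(spec.n_windows):
        structured = idx in structured_idx
        for attempt in range(100):
            chars = _random_rna(
                rng_win, WINDOW_LENGTH, spec.gc_background, spec.background_alphabet
            )
            chars[SITE_START:SITE_END] = list(site_seq)
            if structured:
                arm = "".join(chars[left.start : left.stop])
                chars[right.start : right.stop] = list(reverse_complement(arm))
            planted = bool(
                rng_motif.random()
                < (spec.motif_prob_top if structured else spec.motif_prob_rest)
            )
            motif_start = -1
            if planted:
                motif_start = int(allowed[rng_motif.integers(len(allowed))])
                if not (
                    motif_start + k <= SITE_START or motif_start >= SITE_END
                ):  # pragma: no cover - allowed starts exclude the site
                    logger.info("motif/site collision, regenerating window %d", idx)
                    continue
                chars[motif_start : motif_start + k] = list(motif)
            break
        gene_id = f"G{idx:04d}"
        windows.append(
            TargetWindow(
                window_id=f"W{idx:04d}",
                gene_id=gene_id,
                sequence="".join(chars),
                site_start=SITE_START,
                site_end=SITE_END,
                utr_start=0,
            )
        )
        truth_rows.append((f"W{idx:04d}", gene_id, structured, planted, motif_start))
    truth = pd.DataFrame(
        truth_rows,
        columns=["window_id", "gene_id", "structured", "motif_planted", "motif_start"],
    )
    return windows, truth


MIRNA_ID = "mir-syn"
RBP_ID = "RBP1"


def generate_expression(
    spec: SyntheticSpec,
    phi: list[str],
    targets: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression panels with a cooperative repression effect on Φ.

    Samples split evenly into joint-high, joint-low, miRNA-only-high and
    RBP-only-high quarters; the mixed quarters are what make single-regulator
    sample orderings genuinely underperform the joint ordering.  Φ rows are
    shifted down by ``effect_size * noise_sd`` in joint-high samples only.
    Returns (mRNA matrix including the RBP proxy row, miRNA matrix).
    """
    if not set(phi) <= set(targets):
        raise ValueError("phi must be a subset of targets")
    rng = _rng(spec, _STREAM_EXPRESSION)
    n = spec.n_samples
    n_jh = n // 4
    n_jl = n // 4
    n_mh = n // 4                # miRNA high only
    n_rh = n - n_jh - n_jl - n_mh  # RBP high only
    if n_jh == 0:
        raise ValueError("no joint-high samples; increase n_samples")
    groups = (
        ["jh"] * n_jh + ["jl"] * n_jl + ["mh"] * n_mh + ["rh"] * n_rh
    )
    rng.shuffle(groups)
    sample_ids = [f"S{i:02d}" for i in range(n)]
    high = 4.0 * spec.noise_sd
    x = np.array([high if g in ("jh", "mh") else 0.0 for g in groups])
    y = np.array([high if g in ("jh", "rh") else 0.0 for g in groups])
    x = x + rng.normal(0.0, spec.noise_sd, size=n)
    y = y + rng.normal(0.0, spec.noise_sd, size=n)

    jh_mask = np.array([g == "jh" for g in groups])
    phi_set = set(phi)
    rows = {}
    for t in targets:
        base = rng.normal(0.0, spec.noise_sd, size=n)
        if t in phi_set:
            base = base - spec.effect_size * spec.noise_sd * jh_mask
        rows[t] = base
    rows[RBP_ID] = y
    mrna = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    mirna = pd.DataFrame([x], index=[MIRNA_ID], columns=sample_ids)
    return mrna, mirna


def write_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path,
    family: MirnaFamily = DEFAULT_FAMILY,
) -> dict[str, Path]:
    """Materialize a full synthetic dataset (FASTA + TSVs + config YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    windows, truth = generate_windows(spec, family)
    paths = {
        "windows_fasta": out / "windows.fasta",
        "sites_tsv": out / "sites.tsv",
        "truth_tsv": out / "ground_truth.tsv",
        "validated_tsv": out / "validated_targets.tsv",
        "seeds_tsv": out / "seeds.tsv",
        "mrna_tsv": out / "mrna_expression.tsv",
        "mirna_tsv": out / "mirna_expression.tsv",
        "config_yaml": out / "synthetic_config.yaml",
    }
    # one window per gene: gene ids head the FASTA so downstream reports
    # join directly against the expression matrices
    write_fasta(((w.gene_id, w.sequence) for w in windows), paths["windows_fasta"])
    write_site_table(
        (SeedSite(w.gene_id, w.site_start, w.site_end, "7mer-m8") for w in windows),
        paths["sites_tsv"],
    )
    truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
    validated = truth.loc[truth.motif_planted, "gene_id"]
    validated.to_csv(paths["validated_tsv"], sep="\t", index=False, header=False)
    pd.DataFrame(
        [(family.family_name, family.seed)], columns=["family_name", "seed_7nt"]
    ).to_csv(paths["seeds_tsv"], sep="\t", index=False)

    # the repressed subset is the genuinely least accessible 20%, so the
    # expression panel is coherent with the accessibility ranking
    from .accessibility import rank_windows

    ranked, _ = rank_windows(windows)
    targets = list(truth.gene_id)
    n_phi = max(1, len(targets) // 5)
    phi = [w.gene_id for w in ranked.windows[:n_phi]]
    mrna, mirna = generate_expression(spec, phi, targets)
    mrna.to_csv(paths["mrna_tsv"], sep="\t")
    mirna.to_csv(paths["mirna_tsv"], sep="\t")
    with open(paths["config_yaml"], "w") as fh:
        yaml.safe_dump(asdict(spec), fh)
    return paths
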