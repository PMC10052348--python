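"""Synthetic worlds with known ground truth for every pipeline stage.

Generates (1) a tiered protein family with planted similarity structure,
(2) a compound library from a small medicinal-chemistry fragment
grammar, (3) bioactivities from a known latent linear-plus-interaction
model over compound fingerprint bits and protein descriptor values, and
(4) impedance plate experiments whose net AUCs follow the fixed-slope
inhibition sigmoid. Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import RawActivity, UNIT_PRIORITY
from .descriptors import AMINO_ACIDS, acc_transform, ecfp_fingerprint, residue_scale_encoding

DEFAULT_SEED = 12345

# ---------------------------------------------------------------------------
# protein family

def make_seed_sequence(length: int = 120, seed: int = DEFAULT_SEED) -> str:
    """A random protein sequence used as the family ancestor."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_protein_family(
    seed_sequence: str,
    tier_sizes: Sequence[int] = (3, 4, 4),
    tier_rates: Sequence[float] = (0.02, 0.15, 0.45),
    seed: int = DEFAULT_SEED,
) -> tuple[dict[str, str], dict[str, int]]:
    """Tiered mutants of a seed sequence with decreasing expected identity.

    Tier k sequences are i.i.d. point mutants of the seed at the tier's
    substitution rate; rates must increase across tiers so identity to
    the seed falls tier by tier. Returns (id -> sequence, id -> tier)
    with the untouched seed as ``P_seed`` in tier 0.
    """
    if not seed_sequence:
        raise ValueError("empty seed sequence")
    if len(tier_sizes) != len(tier_rates):
        raise ValueError("tier_sizes and tier_rates must align")
    if any(r < 0 or r >= 0.9 for r in tier_rates):
        raise ValueError("tier rates must lie in [0, 0.9)")
    if any(b < a for a, b in zip(tier_rates, tier_rates[1:])):
        raise ValueError("tier rates must be nondecreasing")
    rng = np.random.default_rng(seed)
    sequences = {"P_seed": seed_sequence}
    tiers = {"P_seed": 0}
    aa = np.array(list(AMINO_ACIDS))
    base = np.array(list(seed_sequence))
    for tier, (size, rate) in enumerate(zip(tier_sizes, tier_rates), start=1):
        for i in range(size):
            mutated = base.copy()
            mask = rng.random(len(base)) < rate
            if mask.any():
                # replace with a uniformly chosen *different* residue
                repl = rng.choice(aa, size=int(mask.sum()))
                same = repl == mutated[mask]
                while same.any():
                    repl[same] = rng.choice(aa, size=int(same.sum()))
                    same = repl == mutated[mask]
                mutated[mask] = repl
            pid = f"P_t{tier}_{i}"
            sequences[pid] = "".join(mutated)
            tiers[pid] = tier
    return sequences, tiers


# ---------------------------------------------------------------------------
# compound library

#: Fragment grammar: aryl cores with one substitution slot, amine-rich
#: linkers, and chain/ring tails. Concatenating linker + tail into the
#: core slot yields valid SMILES by construction.
ARYL_CORES = (
    "c1ccc({})cc1",
    "c1ccc({})c(F)c1",
    "c1ccc({})c(Cl)c1",
    "c1ccc({})c(C)c1",
    "c1ccc({})c(OC)c1",
    "c1ccc2c(c1)cc({})o2",
    "c1ccc2c(c1)cc({})s2",
    "c1ccnc({})c1",
    "c1ccc({})nc1",
    "c1csc({})c1",
)
LINKERS = (
    "CN",
    "CCN",
    "CC(C)N",
    "CCCN",
    "CC(O)CN",
    "CCN(C)",
    "C(=O)N",
    "CC(=O)N",
    "COCCN",
    "CNC(=O)",
)
TAILS = (
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "CC(C)C",
    "CCO",
    "C1CC1",
    "C1CCC1",
    "C1CCCC1",
    "C1CCCCC1",
    "Cc1ccccc1",
    "CCc1ccccc1",
)


def generate_compound_library(
    n: int,
    seed: int = DEFAULT_SEED,
    grammar: tuple[Sequence[str], Sequence[str], Sequence[str]] = (ARYL_CORES, LINKERS, TAILS),
) -> list[str]:
    """Sample n SMILES from the fragment grammar (core + linker + tail).

    Outputs are valid and standardizable; duplicates are allowed.
    """
    cores, linkers, tails = grammar
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        core = cores[rng.integers(len(cores))]
        linker = linkers[rng.integers(len(linkers))]
        tail = tails[rng.integers(len(tails))]
        out.append(core.format(linker + tail))
    return out


# ---------------------------------------------------------------------------
# bioactivities

@dataclass
class BioactivityTruth:
    compound_weights: np.ndarray
    protein_weights: np.ndarray
    interaction_weights: tuple[np.ndarray, np.ndarray] | None
    signal_sd: float
    noise_sd: float
    decoy_proteins: frozenset[str]
    fp_radius: int
    fp_bits: int


def _protein_descriptor_table(sequences: Mapping[str, str]) -> dict[str, np.ndarray]:
    ids = sorted(sequences)
    width = max(len(sequences[p]) for p in ids)
    aligned = [sequences[p].ljust(width, "-") for p in ids]
    mats = residue_scale_encoding(aligned)
    return {p: acc_transform(m, max_lag=3) for p, m in zip(ids, mats)}


def generate_bioactivity(
    sequences: Mapping[str, str],
    compounds: Sequence[str],
    n_records: int = 2000,
    signal_sd: float = 1.0,
    noise_sd: float = 0.5,
    interaction_scale: float = 0.2,
    year_range: tuple[int, int] = (2000, 2015),
    decoy_proteins: frozenset[str] = frozenset(),
    duplicate_fraction: float = 0.05,
    fp_radius: int = 2,
    fp_bits: int = 256,
    baseline: float = 6.5,
    seed: int = DEFAULT_SEED,
) -> tuple[list[RawActivity], BioactivityTruth]:
    """Bioactivities from a latent compound x protein model.

    pChEMBL = baseline + signal_sd * z(w.compound_bits + v.protein_desc
    + interaction) + Gaussian(0, noise_sd); the signal term is
    standardized over the sampled pairs so signal_sd / noise_sd directly
    sets the attainable R2 (defaults give signal fraction 0.8). Records
    of ``decoy_proteins`` have their labels permuted among themselves, so
    their marginal distribution is intact but carries no signal. Activity
    types are assigned round-robin to exercise the unit-priority rule,
    and a fraction of pairs is emitted twice to exercise duplicate
    averaging.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be nonnegative")
    rng = np.random.default_rng(seed)
    proteins = sorted(sequences)
    unique_compounds = sorted(set(compounds))
    fps = {s: ecfp_fingerprint(s, fp_radius, fp_bits).astype(float) for s in unique_compounds}
    pdesc = _protein_descriptor_table(sequences)
    pdesc_dim = len(next(iter(pdesc.values())))

    w = rng.normal(size=fp_bits) / np.sqrt(fp_bits)
    v = rng.normal(size=pdesc_dim) / np.sqrt(pdesc_dim)
    if interaction_scale > 0:
        wi = rng.normal(size=fp_bits) / np.sqrt(fp_bits)
        vi = rng.normal(size=pdesc_dim) / np.sqrt(pdesc_dim)
        interaction: tuple[np.ndarray, np.ndarray] | None = (wi, vi)
    else:
        interaction = None

    n_pairs = len(proteins) * len(unique_compounds)
    n_records = min(n_records, n_pairs)
    pair_idx = rng.choice(n_pairs, size=n_records, replace=False)
    pairs = [(unique_compounds[i % len(unique_compounds)], proteins[i // len(unique_compounds)])
             for i in pair_idx]

    raw_signal = np.empty(n_records)
    for i, (smi, pid) in enumerate(pairs):
        s = float(w @ fps[smi] + v @ pdesc[pid])
        if interaction is not None:
            s += interaction_scale * float(interaction[0] @ fps[smi]) * float(interaction[1] @ pdesc[pid])
        raw_signal[i] = s
    z = (raw_signal - raw_signal.mean()) / (raw_signal.std() or 1.0)
    labels = baseline + signal_sd * z + rng.normal(scale=noise_sd, size=n_records)

    decoy_rows = np.array([pid in decoy_proteins for _, pid in pairs])
    if decoy_rows.any():
        permuted = labels[decoy_rows].copy()
        rng.shuffle(permuted)
        labels[decoy_rows] = permuted

    records = []
    for i, ((smi, pid), value) in enumerate(zip(pairs, labels)):
        records.append(
            RawActivity(
                compound_id=f"cpd{i}",
                smiles=smi,
                target_id=pid,
                activity_type=UNIT_PRIORITY[i % len(UNIT_PRIORITY)],
                value=float(value),
                year=int(rng.integers(year_range[0], year_range[1] + 1)),
            )
        )
    n_dup = int(duplicate_fraction * n_records)
    for i in range(n_dup):
        src = records[int(rng.integers(n_records))]
        records.append(
            RawActivity(
                compound_id=src.compound_id + "_dup",
                smiles=src.smiles,
                target_id=src.target_id,
                activity_type=src.activity_type,
                value=src.value + float(rng.normal(scale=0.1)),
                year=src.year,
            )
        )
    truth = BioactivityTruth(
        compound_weights=w, protein_weights=v, interaction_weights=interaction,
        signal_sd=signal_sd, noise_sd=noise_sd, decoy_proteins=frozenset(decoy_proteins),
        fp_radius=fp_radius, fp_bits=fp_bits,
    )
    return records, truth


# ---------------------------------------------------------------------------
# impedance experiments

def _response_shape(t: np.ndarray, t0: float) -> np.ndarray:
    """Post-stimulation transient: zero before t0, smooth bump after."""
    dt = np.clip(t - t0, 0.0, None)
    return (dt / 5.0) * np.exp(1.0 - dt / 5.0)


def generate_impedance_experiment(
    true_pic50: Mapping[str, float],
    concentrations_m: Sequence[float] = (1e-11, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5),
    noise_sd_pct: float = 0.0,
    duplicates: int = 2,
    t_substrate_min: float = 60.0,
    total_min: float = 95.0,
    dt_min: float = 1.0,
    amp_ne: float = 0.5,
    amp_ref: float = 2.0,
    baseline_ci: float = 1.5,
    z0_ohm: float = 30.0,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Simulated impedance plate whose AUCs follow the fixed-slope sigmoid.

    Each sample well's response amplitude is
    amp_ne + (amp_ref - amp_ne) * 1/(1 + 10^-(log10 c + pIC50)) plus
    Gaussian amplitude noise of ``noise_sd_pct`` percent of the
    ne-control-to-reference window. Vehicle/vehicle, substrate-only
    (ne_control), and reference wells are included. Returns long-format
    traces, the plate map, and the truth (compound -> pIC50).
    """
    if any(c <= 0 for c in concentrations_m):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_min + dt_min / 2, dt_min)
    growth = 0.2 + 0.8 * np.clip(t / t_substrate_min, 0.0, 1.0)
    shape = _response_shape(t, t_substrate_min)

    trace_rows, map_rows = [], []
    well_no = [0]

    def add_well(role: str, compound_id: str, conc: float, amplitude: float) -> None:
        well_no[0] += 1
        well = f"W{well_no[0]:03d}"
        ci_scale = baseline_ci * float(rng.uniform(0.8, 1.2))
        ci = ci_scale * (growth + amplitude * shape)
        z = z0_ohm * float(rng.uniform(0.9, 1.1)) + 15.0 * ci
        # analyze_experiment uses the first sample as Z0, so emit a t=0 row
        for ti, zi in zip(t, z):
            trace_rows.append({"well": well, "time_min": ti, "impedance_ohm": zi})
        map_rows.append(
            {"well": well, "role": role, "compound_id": compound_id, "concentration_m": conc}
        )

    span = amp_ref - amp_ne
    for _ in range(duplicates):
        add_well("vehicle", "vehicle", 0.0, 0.0)
        add_well("ne_control", "NE", 0.0, amp_ne)
        add_well("reference", "reference", 1e-5, amp_ref)
    for cid, pic50 in true_pic50.items():
        for conc in concentrations_m:
            frac = 1.0 / (1.0 + 10.0 ** (-(np.log10(conc) + pic50)))
            for _ in range(duplicates):
                amp = amp_ne + span * frac
                if noise_sd_pct > 0:
                    amp += span * (noise_sd_pct / 100.0) * float(rng.normal())
                add_well("sample", cid, conc, amp)

    traces = pd.DataFrame(trace_rows)
    plate_map = pd.DataFrame(map_rows)
    return traces, plate_map, dict(true_pic50)


# ---------------------------------------------------------------------------
# assembled worlds

@dataclass
class SyntheticWorld:
    seed: int
    sequences: dict[str, str]
    tiers: dict[str, int]
    compounds: list[str]
    records: list[RawActivity]
    truth: BioactivityTruth
    seed_protein: str = "P_seed"
    decoy_proteins: frozenset[str] = field(default_factory=frozenset)


def make_world(
    name: str = "small",
    seed: int = DEFAULT_SEED,
    decoy_tiers: tuple[int, ...] = (3,),
) -> SyntheticWorld:
    """The standard benchmark world.

    "small": 12 proteins in 3 tiers around the seed (tight homologs /
    mid family / distant proteins), 400 grammar compounds, 2,000
    bioactivity records. Records of the distant tier are label-permuted
    decoys, so predictive signal is shared only by the seed, its tight
    homologs, and the mid tier.
    """
    sizes = {"small": ((3, 4, 4), 400, 2000), "tiny": ((2, 3, 3), 120, 400)}
    if name not in sizes:
        raise ValueError(f"unknown world {name!r}; options: {sorted(sizes)}")
    tier_sizes, n_compounds, n_records = sizes[name]
    seq0 = make_seed_sequence(length=120, seed=seed)
    sequences, tiers = generate_protein_family(seq0, tier_sizes=tier_sizes, seed=seed + 1)
    compounds = generate_compound_library(n_compounds, seed=seed + 2)
    decoys = frozenset(p for p, t in tiers.items() if t in decoy_tiers)
    records, truth = generate_bioactivity(
        sequences, compounds, n_records=n_records,
        decoy_proteins=decoys, seed=seed + 3,
    )
    return SyntheticWorld(
        seed=seed, sequences=sequences, tiers=tiers, compounds=compounds,
        records=records, truth=truth, decoy_proteins=decoys,
    )


def raw_records_frame(records: Sequence[RawActivity]) -> pd.DataFrame:
    """RawActivity list as the CSV-shaped activity table."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "target_id": [r.target_id for r in records],
            "activity_type": [r.activity_type for r in records],
            "pchembl": [r.value for r in records],
            "year": [r.year for r in records],
        }
    )
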