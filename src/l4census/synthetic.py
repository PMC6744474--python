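"""Synthetic-data generators with exact ground truth.

Every input the pipeline consumes can be generated here: current-clamp
sweep sets with known passive and firing properties, branching neuronal
trees with tracked morphometrics, clustered negative-binomial count
matrices with a matching reference atlas, Bernoulli connectivity records,
and barrel-intensity profiles with drift. Generators are pure functions of
their parameters and a seed: identical inputs give identical outputs, and
each returns the ground truth needed to score the downstream operation.

The sweep generator deliberately uses stereotyped action-potential
templates (piecewise-linear rise and fall, exponential recovery) on top of
a leaky-integrator subthreshold response, so that the true threshold,
amplitude, width, AHP, and spike times are known exactly rather than
emerging from a biophysical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .ephys import Sweep, SweepSet
from .morphology import Morphology
from .patchseq import ReferenceAtlas

__all__ = [
    "EphysCellParams",
    "gen_sweep_set",
    "gen_morphology",
    "gen_counts",
    "gen_connectivity",
    "gen_barrel_profile",
]


# ---------------------------------------------------------------------------
# sweep sets


@dataclass
class EphysCellParams:
    """Ground-truth cell parameters for the sweep generator.

    Units: mV, pA, ms. ``fi_slope`` is spikes per pA above rheobase over
    the whole stimulus window; ``adaptation`` is the ratio of consecutive
    interspike intervals (1 = regular train); ``sag_amplitude`` scales the
    transient extra deflection of hyperpolarizing responses (0 = no sag).
    """

    rmp: float = -70.0
    r_in_MOhm: float = 150.0
    tau_ms: float = 20.0
    rheobase_pA: float = 70.0
    fi_slope: float = 0.15
    adaptation: float = 1.3
    sag_amplitude: float = 0.2
    isi_min_ms: float = 8.0
    ap_amplitude: float = 60.0
    ap_rise_ms: float = 0.6
    ap_fall_ms: float = 1.2
    ahp_depth: float = 12.0
    adp_mV: float = 0.0
    latency_ms: float = 40.0
    noise_sd: float = 0.1


@dataclass
class SweepSetTruth:
    """The 13 true feature values implied by the generator parameters."""

    features: dict = field(default_factory=dict)


def _ap_template(p: EphysCellParams, dt_ms: float) -> np.ndarray:
    """Stereotyped AP waveform relative to its starting (threshold) voltage."""
    rise = np.linspace(0.0, p.ap_amplitude, max(2, int(round(p.ap_rise_ms / dt_ms)) + 1))
    fall = np.linspace(
        p.ap_amplitude, -p.ahp_depth, max(2, int(round(p.ap_fall_ms / dt_ms)) + 1)
    )[1:]
    pieces = [rise, fall]
    rec_from = -p.ahp_depth
    if p.adp_mV > 0:
        # depolarizing hump: rise above the trough, then dip part-way back
        # before the recovery — a genuine local maximum after the trough
        t_up = np.arange(1, int(round(3.0 / dt_ms)) + 1) * dt_ms
        up = -p.ahp_depth + p.adp_mV * np.sin(np.pi * t_up / (2 * t_up[-1]))
        t_dn = np.arange(1, int(round(2.0 / dt_ms)) + 1) * dt_ms
        dn = -p.ahp_depth + p.adp_mV - (p.adp_mV / 2.0) * np.sin(
            np.pi * t_dn / (2 * t_dn[-1])
        )
        pieces.extend([up, dn])
        rec_from = -p.ahp_depth + p.adp_mV / 2.0
    # the recovery is deliberately fast so each AP waveform completes before
    # the shortest permitted ISI: overlapping tails would create voltage
    # discontinuities at the next AP onset
    rec_t = np.arange(1, int(round(12.0 / dt_ms)) + 1) * dt_ms
    rec = rec_from * np.exp(-rec_t / 1.2)
    pieces.append(rec)
    return np.concatenate(pieces)


def _hyper_deflection(t_ms: np.ndarray, d_ss: float, p: EphysCellParams) -> np.ndarray:
    """Deflection time course of a hyperpolarizing step (positive = downward).

    First phase: single-exponential approach (time constant tau) to the
    peak deflection ``d_peak = d_ss * (1 + sag_amplitude)``; after five
    time constants the deflection relaxes back toward ``d_ss`` with a slow
    sag time constant. With ``sag_amplitude = 0`` this is a plain
    exponential charging curve.
    """
    d_peak = d_ss * (1.0 + p.sag_amplitude)
    t_star = 5.0 * p.tau_ms
    d = d_peak * (1.0 - np.exp(-t_ms / p.tau_ms))
    if p.sag_amplitude > 0:
        late = t_ms > t_star
        d_at = d_peak * (1.0 - np.exp(-t_star / p.tau_ms))
        d[late] = d_ss + (d_at - d_ss) * np.exp(-(t_ms[late] - t_star) / 80.0)
    return d


def _spike_times_ms(p: EphysCellParams, current: float, window_ms: float) -> np.ndarray:
    """Spike times with geometric ISI adaptation, filling the stimulus window.

    The target count follows the f-I line; if the geometric ISI schedule
    would push the first ISI below ``isi_min_ms`` (unphysiologically fast
    firing), the count saturates at the largest train that fits.
    """
    n = int(round(p.fi_slope * (current - p.rheobase_pA)))
    if current <= p.rheobase_pA or n <= 0:
        return np.array([])
    lat = p.latency_ms
    avail = window_ms - lat - 10.0
    a = p.adaptation
    # ISI schedule: isi1, then a*isi1 for every later interval — the
    # adaptation index ISI2/ISI1 equals a exactly while long trains still
    # fill the window linearly in the target count
    while n > 2:
        isi1 = avail / (1.0 + a * (n - 2))
        if min(isi1, a * isi1) >= p.isi_min_ms:
            break
        n -= 1
    if n == 1:
        return np.array([lat])
    if n == 2:
        return np.array([lat, lat + avail])
    isis = np.concatenate([[isi1], np.full(n - 2, a * isi1)])
    return lat + np.concatenate([[0.0], np.cumsum(isis)])


def sample_cell_params(rng: np.random.Generator) -> EphysCellParams:
    """Draw one cell's ground-truth parameters from realistic adult-cortex ranges.

    Resting potentials -75..-60 mV, input resistances 80-300 MOhm, membrane
    time constants 12-35 ms, rheobases 30-150 pA, f-I gains 0.15-0.35
    spikes/pA (in steps of 0.05, i.e. 3-7 extra spikes per 20 pA increment),
    adaptation indices 0.9-2, sag amplitudes up to 0.5, and an
    after-depolarization in roughly a third of cells.
    """
    return EphysCellParams(
        rmp=rng.uniform(-75.0, -60.0),
        r_in_MOhm=rng.uniform(80.0, 300.0),
        tau_ms=rng.uniform(12.0, 35.0),
        rheobase_pA=rng.uniform(30.0, 150.0),
        fi_slope=float(rng.choice([0.15, 0.2, 0.25, 0.3, 0.35])),
        adaptation=rng.uniform(0.9, 2.0),
        sag_amplitude=rng.uniform(0.0, 0.5),
        ahp_depth=rng.uniform(5.0, 20.0),
        ap_amplitude=rng.uniform(55.0, 85.0),
        latency_ms=rng.uniform(10.0, 100.0),
        adp_mV=float(rng.choice([0.0, 0.0, 3.0])),
    )


def gen_sweep_set(
    params: EphysCellParams | None = None,
    seed: int = 0,
    currents: np.ndarray | None = None,
    protocol: str = "fixed_holding",
    dt_ms: float = 0.1,
    pre_ms: float = 150.0,
    stim_ms: float = 600.0,
    post_ms: float = 250.0,
) -> tuple[SweepSet, dict]:
    """Generate one cell's sweep set plus its true 13-feature dictionary.

    The subthreshold response is a leaky integrator with an optional sag
    term; above rheobase, stereotyped AP templates are superimposed at
    spike times with geometric interspike-interval adaptation, so every
    returned truth value is exact by construction. Under
    ``variable_holding`` each sweep gets a random holding current, shifting
    its pre-stimulus baseline off the resting potential.
    """
    p = params or EphysCellParams()
    rng = np.random.default_rng(seed)
    if currents is None:
        currents = np.arange(-200.0, 401.0, 20.0)
    currents = np.asarray(currents, dtype=float)
    if p.rheobase_pA > currents.max():
        import warnings

        warnings.warn("rheobase outside the current ladder: no spiking sweeps")
    r_gohm = p.r_in_MOhm / 1000.0  # mV per pA
    n = int(round((pre_ms + stim_ms + post_ms) / dt_ms)) + 1
    t_ms = np.arange(n) * dt_ms
    onset, offset = pre_ms, pre_ms + stim_ms
    stim_mask = (t_ms >= onset) & (t_ms <= offset)
    t_rel = t_ms[stim_mask] - onset
    template = _ap_template(p, dt_ms)

    sweeps = []
    truth: dict = {}
    first_spiking_done = False
    max_count = 0
    noiseless_lowest_hyper = None
    for current in currents:
        if current == 0.0:
            continue
        hold = rng.uniform(-30.0, 30.0) if protocol == "variable_holding" else 0.0
        # holding shifts the pre-stimulus baseline; the recorded current is
        # the total injected current during the step, so the steady state
        # during the stimulus depends on the step current only
        base = p.rmp + r_gohm * hold
        v = np.full(n, base)
        if current < 0:
            d_ss = base - (p.rmp + r_gohm * current)  # positive downward deflection
            defl = _hyper_deflection(t_rel, d_ss, p)
            v[stim_mask] = base - defl
            post = t_ms > offset
            v[post] = v[stim_mask][-1] + (base - v[stim_mask][-1]) * (
                1 - np.exp(-(t_ms[post] - offset) / p.tau_ms)
            )
        else:
            # depolarization saturates near threshold
            d_ss = max(0.0, min(p.rmp + r_gohm * current - base, 15.0))
            v[stim_mask] = base + d_ss * (1.0 - np.exp(-t_rel / p.tau_ms))
            post = t_ms > offset
            v[post] = v[stim_mask][-1] + (base - v[stim_mask][-1]) * (
                1 - np.exp(-(t_ms[post] - offset) / p.tau_ms)
            )
            spikes = _spike_times_ms(p, current, stim_ms)
            max_count = max(max_count, spikes.size)
            backbone = v.copy()
            starts = [int(round((onset + s_ms) / dt_ms)) for s_ms in spikes]
            ends = []
            for i0 in starts:
                i1 = min(i0 + template.size, n)
                # each AP rides on the subthreshold backbone at its own onset,
                # overwriting any residual tail of the previous AP
                local = backbone[i0]
                v[i0:i1] = local + template[: i1 - i0]
                ends.append(i1)
                if not first_spiking_done:
                    truth.setdefault("ap_threshold", float(local))
            # ramp each template tail back onto the (risen) backbone over a
            # few ms: a hard reversion would be a voltage step steep enough
            # to mimic a spike upstroke
            nb = int(round(3.0 / dt_ms))
            for k, i1 in enumerate(ends):
                nxt = starts[k + 1] if k + 1 < len(starts) else n
                if i1 >= nxt:
                    continue
                j1 = min(i1 + nb, nxt, n - 1)
                if j1 > i1:
                    v[i1 - 1 : j1 + 1] = np.linspace(v[i1 - 1], v[j1], j1 - i1 + 2)
            if spikes.size and not first_spiking_done:
                truth["latency"] = float(spikes[0])
                first_spiking_done = True
        if current < 0 and (
            noiseless_lowest_hyper is None or current < noiseless_lowest_hyper[0]
        ):
            noiseless_lowest_hyper = (current, v.copy(), base)
        v_noisy = v + rng.normal(0.0, p.noise_sd, size=n)
        sweeps.append(
            Sweep(
                time=t_ms / 1000.0,
                voltage=v_noisy,
                current_pA=float(current),
                onset_s=onset / 1000.0,
                offset_s=offset / 1000.0,
            )
        )

    sweep_set = SweepSet(sweeps=tuple(sweeps), protocol=protocol)

    truth["resting_potential"] = p.rmp
    truth["input_resistance"] = p.r_in_MOhm
    truth["rheobase"] = p.rheobase_pA
    truth["ap_amplitude"] = p.ap_amplitude
    # half-height crossings: mid-rise, and the point where the linear fall
    # from the peak to the trough passes half amplitude
    truth["ap_width"] = p.ap_rise_ms / 2.0 + p.ap_fall_ms * (p.ap_amplitude / 2.0) / (
        p.ap_amplitude + p.ahp_depth
    )
    truth["ahp"] = p.ahp_depth
    truth["adp"] = p.adp_mV
    truth["adaptation_index"] = p.adaptation if max_count >= 3 else np.nan
    truth["max_spike_count"] = float(max_count)
    truth["tau"] = p.tau_ms
    if noiseless_lowest_hyper is not None:
        _, v_clean, base = noiseless_lowest_hyper
        i0 = int(round(onset / dt_ms))
        i1 = int(round(offset / dt_ms))
        i_ss = i1 - int(round(100.0 / dt_ms))
        peak_defl = base - v_clean[i0:i1].min()
        steady_defl = base - v_clean[i_ss:i1].mean()
        truth["sag_ratio"] = float(peak_defl / steady_defl) if steady_defl else np.nan
    else:
        truth["sag_ratio"] = np.nan
    return sweep_set, truth


# ---------------------------------------------------------------------------
# morphologies


def gen_morphology(
    seed: int = 0,
    n_segments: int = 30,
    branch_prob: float = 0.5,
    segment_length_mean: float = 40.0,
    step_um: float = 5.0,
    wiggle: float = 0.15,
    z_drift: float = 0.0,
    n_stems: int = 2,
) -> tuple[Morphology, dict]:
    """Grow a random tree by segment addition; return it with tracked truth.

    Active tips either branch into two daughters (probability
    ``branch_prob``) or terminate, until ``n_segments`` segments have been
    grown. Segments are polylines of ``step_um`` steps with angular wiggle
    (giving tortuosity > 1) and an optional systematic drift along Z that
    mimics type-specific laminar targeting. The truth dictionary tracks
    stems, branch points, tips, total length, and the maximal segment
    length exactly, as accumulated during growth.
    """
    if branch_prob < 0 or branch_prob > 1:
        raise ValueError("branch_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]  # soma at the origin
    next_id = 2
    total_len = 0.0
    seg_lengths = []
    n_branch_points = 0
    n_tips = 0

    def random_dir():
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    # queue entries: (parent node id, position, direction)
    queue = [(1, np.zeros(3), random_dir()) for _ in range(n_stems)]
    grown = 0
    while queue and grown < n_segments:
        parent_id, pos, direction = queue.pop(0)
        length = max(step_um, rng.normal(segment_length_mean, segment_length_mean / 4))
        n_steps = max(1, int(round(length / step_um)))
        seg_len = 0.0
        pid = parent_id
        for _ in range(n_steps):
            turn = rng.normal(0.0, wiggle, size=3)
            direction = direction + turn
            direction[2] += z_drift
            direction = direction / np.linalg.norm(direction)
            new_pos = pos + direction * step_um
            seg_len += step_um
            rows.append((next_id, 3, *new_pos, 1.0, pid))
            pid = next_id
            next_id += 1
            pos = new_pos
        total_len += seg_len
        seg_lengths.append(seg_len)
        grown += 1
        can_branch = grown + len(queue) < n_segments - 1
        if can_branch and rng.random() < branch_prob:
            n_branch_points += 1
            for _ in range(2):
                queue.append((pid, pos.copy(), random_dir()))
        else:
            n_tips += 1
    # anything left in the queue never grew: its parent stays a tip only if
    # it has no other children; count tips from the final structure instead
    df = pd.DataFrame(rows, columns=["id", "struct", "x", "y", "z", "radius", "parent"])
    m = Morphology(df)
    truth = {
        "n_stems": n_stems,
        "n_branch_points": sum(
            1 for i in df["id"] if i != 1 and len(m.children(int(i))) >= 2
        ),
        "n_tips": sum(1 for i in df["id"] if i != 1 and len(m.children(int(i))) == 0),
        "total_length": total_len,
        "max_segment_length": max(seg_lengths) if seg_lengths else 0.0,
        "segment_lengths": seg_lengths,
    }
    return m, truth


# ---------------------------------------------------------------------------
# count matrices


def gen_counts(
    seed: int = 0,
    n_cells: int = 500,
    n_genes: int = 300,
    n_clusters: int = 5,
    depth: float = 10000.0,
    dispersion: float = 0.2,
    centroid_sd: float = 1.5,
    low_depth_fraction: float = 0.0,
    n_reference_per_cluster: int = 40,
    n_variable_genes: int = 100,
) -> tuple[ad.AnnData, np.ndarray, ReferenceAtlas]:
    """Clustered negative-binomial counts plus a matching reference atlas.

    Cluster centroids are log-normal gene-expression profiles; counts are
    negative-binomial with a shared dispersion around the depth-scaled
    centroid, so dropout arises from the count distribution itself. A
    held-out reference half (``n_reference_per_cluster`` cells per
    cluster) builds the atlas: per-cluster mean log2(x+1) centroids, a
    2-D embedding with one Gaussian blob per cluster, and a
    most-variable-gene list. ``low_depth_fraction`` of the query cells are
    generated with library size below the QC threshold of 1500.
    """
    if n_clusters < 2:
        raise ValueError("need at least two clusters")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    centroids = np.empty((n_clusters, n_genes))
    for k in range(n_clusters):
        centroids[k] = base * rng.lognormal(mean=0.0, sigma=centroid_sd, size=n_genes)
    centroids /= centroids.sum(axis=1, keepdims=True)

    def sample(cluster: int, n: int, cell_depth: float) -> np.ndarray:
        mu = centroids[cluster] * cell_depth
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p, size=(n, n_genes))

    labels = rng.integers(0, n_clusters, size=n_cells)
    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    n_low = int(round(low_depth_fraction * n_cells))
    for i, k in enumerate(labels):
        d = rng.uniform(200.0, 1000.0) if i < n_low else depth
        counts[i] = sample(int(k), 1, d)[0]
    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=pd.DataFrame(index=[f"cell{i:04d}" for i in range(n_cells)]),
        var=pd.DataFrame(index=[f"gene{j:04d}" for j in range(n_genes)]),
    )
    adata.obs["true_cluster"] = [f"C{k}" for k in labels]

    # reference half
    ref_labels = np.repeat(np.arange(n_clusters), n_reference_per_cluster)
    ref_counts = np.vstack(
        [sample(int(k), 1, depth) for k in ref_labels]
    )
    log_ref = np.log2(ref_counts + 1.0)
    cent = np.vstack(
        [log_ref[ref_labels == k].mean(axis=0) for k in range(n_clusters)]
    )
    gene_names = list(adata.var_names)
    cent_df = pd.DataFrame(cent, index=[f"C{k}" for k in range(n_clusters)], columns=gene_names)

    from .patchseq import select_variable_genes

    try:
        var_genes = select_variable_genes(ref_counts, n_variable_genes, gene_names)
    except ValueError:
        var_genes = gene_names
    emb_centers = rng.uniform(-20, 20, size=(n_clusters, 2))
    emb = emb_centers[ref_labels] + rng.normal(0, 1.0, size=(ref_labels.size, 2))
    ref = ad.AnnData(
        X=ref_counts.astype(np.int64),
        obs=pd.DataFrame(
            {"cluster": [f"C{k}" for k in ref_labels]},
            index=[f"ref{i:04d}" for i in range(ref_labels.size)],
        ),
        var=pd.DataFrame(index=gene_names),
    )
    ref.obsm["embedding"] = emb
    atlas = ReferenceAtlas(centroids=cent_df, variable_genes=var_genes, reference_cells=ref)
    return adata, np.array([f"C{k}" for k in labels], dtype=object), atlas


# ---------------------------------------------------------------------------
# connectivity records


def gen_connectivity(
    pair_specs: list[dict] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Bernoulli connectivity records from per-pair probabilities.

    ``pair_specs`` entries: dicts with pre_type, post_type, area, modality,
    n_tested, probability. Defaults emulate the tested tallies of a
    two-area excitatory/SOM+ survey.
    """
    if pair_specs is None:
        pair_specs = [
            dict(pre_type="SOM", post_type="exc", area="V1", modality="chemical", n_tested=142, probability=0.21),
            dict(pre_type="SOM", post_type="exc", area="S1", modality="chemical", n_tested=64, probability=0.27),
            dict(pre_type="exc", post_type="SOM", area="V1", modality="chemical", n_tested=142, probability=0.0),
            dict(pre_type="exc", post_type="SOM", area="S1", modality="chemical", n_tested=64, probability=0.125),
        ]
    rng = np.random.default_rng(seed)
    rows = []
    for spec in pair_specs:
        p = spec["probability"]
        if not 0.0 <= p <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        draws = rng.random(spec["n_tested"]) < p
        for hit in draws:
            rows.append(
                (
                    spec["pre_type"],
                    spec["post_type"],
                    spec["area"],
                    spec.get("modality", "chemical"),
                    True,
                    bool(hit),
                )
            )
    return pd.DataFrame(
        rows, columns=["pre_type", "post_type", "area", "modality", "tested", "connected"]
    )


# ---------------------------------------------------------------------------
# barrel profiles


def gen_barrel_profile(
    centers_um=(850.0, 1650.0),
    seed: int = 0,
    length_um: float = 2500.0,
    pixel_um: float = 5.0,
    bump_sigma_um: float = 150.0,
    bump_amplitude: float = 1.0,
    drift_slope: float = 0.0,
    noise_sd: float = 0.0,
    signal: str = "tdTomato",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum-of-Gaussian-bumps intensity profile with drift and noise.

    Returns ``(positions_um, intensity, true_centers)``. The cytochrome
    variant has inverted contrast (bright background, dark barrels).
    ``drift_slope`` is intensity units per um. Bumps closer together than
    twice their width trigger a resolution warning.
    """
    centers = np.asarray(centers_um, dtype=float)
    if np.any(centers < 0) or np.any(centers > length_um):
        raise ValueError("barrel centers must lie within the profile domain")
    if centers.size > 1 and np.any(np.diff(np.sort(centers)) < 2 * bump_sigma_um):
        import warnings

        warnings.warn("barrel bumps overlap below the detection resolution")
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, length_um + pixel_um / 2, pixel_um)
    y = np.zeros_like(x)
    for c in centers:
        y += bump_amplitude * np.exp(-((x - c) ** 2) / (2 * bump_sigma_um**2))
    y += drift_slope * x
    y += rng.normal(0.0, noise_sd, size=x.size)
    if signal == "cytochrome":
        y = y.max() - y  # inverted contrast
    return x, y, np.sort(centers)
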