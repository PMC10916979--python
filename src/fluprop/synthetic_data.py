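"""Synthetic lexicons, fluency cohorts, and EEG with plantable effects.

Every input the pipeline consumes can be generated here with the
statistical structure the analyses assume, so all stages are testable end
to end without clinical data:

- a Zipfian lexicon whose properties are rank-correlated through a Gaussian
  copula (frequent words tend to be shorter, more familiar, more imageable,
  and sit higher in the taxonomy), plus a random rooted hypernym taxonomy;
- cohorts in which a latent per-participant severity drives reduced valid
  response counts and biases word choice toward high-frequency,
  low-granularity, high-neighborhood items (the neighborhood bias in the
  semantic task only), with covariates and cognitive scores (IFS, MoCA)
  linked to severity — an Alzheimer-like profile; a bvFTD-like group gets
  only the count deficit;
- multichannel oscillatory EEG built from shared band-limited sources, with
  a planted sensor cluster whose coupling is reduced in one group
  (occipito-parieto-central-like hypoconnectivity).

Every generator is a pure function of (spec, seed).  Default parameters are
the package's reference cohort: group sizes 32/32/27 (AD-like, bvFTD-like,
controls) and Table-style demographic distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fluprop.eeg_connectivity import BETA_BAND, SegmentedEEG, bandpass_and_segment
from fluprop.fluency_corpus import TASKS, FluencyResponse
from fluprop.lexicon import Lexicon, LexiconEntry, TaxonomyGraph, property_table
import networkx as nx

PHONEME_INVENTORY = tuple("pbtdkgmnlrsfxjwaeiou")

#: AD-like planted effects: property -> (shift in participant-level SD units,
#: tasks affected).  Positive = patients higher.
AD_EFFECTS = {
    "frequency": (0.8, ("phonemic", "semantic")),
    "granularity": (-0.8, ("phonemic", "semantic")),
    "neighborhood": (0.8, ("semantic",)),
}


def _default_demographics() -> dict:
    # mean/sd age and education, female fraction per group
    return {
        "AD": {"age": (75.8, 5.6), "education": (11.6, 4.2), "female": 18 / 32},
        "bvFTD": {"age": (68.9, 7.8), "education": (13.2, 5.0), "female": 17 / 32},
        "HC": {"age": (72.3, 7.3), "education": (13.6, 3.8), "female": 19 / 27},
    }


@dataclass
class SyntheticCohortSpec:
    """Parameters of a generated lexicon + cohort.

    ``effects`` maps group -> property -> (shift, tasks): the planted
    between-group difference in units of the within-group SD of
    participant-level property means, applied in the listed tasks.
    ``property_rank_corr`` gives Spearman correlations among (frequency,
    familiarity, imageability, length, granularity) latents; the generator
    converts them to Gaussian-copula correlations.  ``ifs_link`` is the
    target pooled correlation between latent severity and the IFS score.
    """

    seed: int
    n_per_group: dict = field(default_factory=lambda: {"AD": 32, "bvFTD": 32, "HC": 27})
    effects: dict = field(default_factory=lambda: {"AD": dict(AD_EFFECTS), "bvFTD": {}, "HC": {}})
    count_deficit: dict = field(default_factory=lambda: {"AD": 1.9, "bvFTD": 1.2, "HC": 0.0})
    base_count: tuple = (18.0, 4.0)  # HC mean and SD of per-task valid counts
    severity_mean: dict = field(default_factory=lambda: {"AD": 1.0, "bvFTD": 1.0, "HC": 0.0})
    severity_sd: float = 0.25
    ifs_link: float = 0.7
    ifs_base: float = 21.4
    ifs_slope: float = 7.0
    moca_base: float = 25.7
    moca_slope: float = 9.0
    demographics: dict = field(default_factory=_default_demographics)
    n_words: int = 2000
    zipf_exponent: float = 1.2
    freq_familiarity_rho: float = 0.6
    freq_imageability_rho: float = 0.4
    freq_length_rho: float = -0.5
    freq_granularity_rho: float = -0.4
    missing_rate: float = 0.05
    polysemy_rate: float = 0.05
    invalid_repetition_rate: float = 0.04
    invalid_digit_rate: float = 0.01
    unintelligible_rate: float = 0.01
    #: converts a participant-level SD shift into a per-word softmax
    #: coefficient; approximately 1.2 / sqrt(mean valid count)
    utility_gain: float = 0.28

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("need at least 2 participants per group")
        known = {"frequency", "granularity", "neighborhood", "length", "familiarity", "imageability"}
        for group, eff in self.effects.items():
            bad = set(eff) - known
            if bad:
                raise ValueError(f"unknown properties in effects[{group!r}]: {sorted(bad)}")


def _copula_corr(rank_rho: float) -> float:
    """Latent Gaussian correlation reproducing a target Spearman rho."""
    return float(2.0 * np.sin(np.pi * rank_rho / 6.0))


def make_lexicon(spec: SyntheticCohortSpec) -> tuple[Lexicon, TaxonomyGraph]:
    """Generate a Zipfian lexicon and a random rooted hypernym taxonomy.

    Word frequency follows a Zipf law over ranks; familiarity, imageability,
    phoneme length, and taxonomy depth are tied to the frequency latent by a
    Gaussian copula at the spec's rank correlations.  Each word gets a leaf
    node in a random taxonomy skeleton (acyclic, every node reaches the
    root); a small fraction receive a second, shallower-or-deeper sense.
    Familiarity, imageability, and frequency values are deleted at
    ``missing_rate`` to exercise per-property missingness handling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    n = spec.n_words

    rhos = [
        spec.freq_familiarity_rho,
        spec.freq_imageability_rho,
        spec.freq_length_rho,
        spec.freq_granularity_rho,
    ]
    # latents: z0 frequency, then familiarity / imageability / length / depth
    corr = np.eye(5)
    for k, r in enumerate(rhos, start=1):
        corr[0, k] = corr[k, 0] = _copula_corr(r)
    # mutual correlation among familiarity and imageability
    corr[1, 2] = corr[2, 1] = _copula_corr(0.5)
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValueError("property correlation matrix is not positive definite")
    z = rng.multivariate_normal(np.zeros(5), corr, size=n, method="cholesky")

    # Zipf marginal: rank by the frequency latent, freq per million ~ rank^-a
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(-z[:, 0])] = np.arange(1, n + 1)
    freq_pm = 3.0e4 * ranks.astype(float) ** (-spec.zipf_exponent)
    log_freq = np.log10(freq_pm)
    familiarity = np.clip(4.0 + 1.2 * z[:, 1], 1.0, 7.0)
    imageability = np.clip(4.0 + 1.2 * z[:, 2], 1.0, 7.0)
    lengths = np.clip(np.rint(5.0 + 1.3 * z[:, 3] + rng.normal(0, 0.7, n)), 2, 10).astype(int)
    depths = np.clip(np.rint(5.0 + 1.5 * z[:, 4] + rng.normal(0, 0.7, n)), 2, 9).astype(int)

    inv = np.array(PHONEME_INVENTORY)
    forms: list[str] = []
    phonemes: list[tuple[str, ...]] = []
    seen: set[str] = set()
    for i in range(n):
        for _ in range(100):
            seq = tuple(rng.choice(inv, size=lengths[i]))
            form = "".join(seq)
            if form not in seen:
                break
        else:  # pragma: no cover - inventory large enough in practice
            form = f"{form}{i}x"
            seq = tuple(form)
        seen.add(form)
        forms.append(form)
        phonemes.append(seq)

    miss = rng.random((n, 3)) < spec.missing_rate
    entries = [
        LexiconEntry(
            form=forms[i],
            phonemes=phonemes[i],
            log_freq_pm=None if miss[i, 0] else float(log_freq[i]),
            familiarity=None if miss[i, 1] else float(familiarity[i]),
            imageability=None if miss[i, 2] else float(imageability[i]),
        )
        for i in range(n)
    ]
    lexicon = Lexicon(entries)

    # taxonomy skeleton: internal concept nodes at depths 1..8
    g = nx.DiGraph()
    root = "entity"
    g.add_node(root)
    by_depth: dict[int, list[str]] = {0: [root]}
    n_internal = max(60, n // 20)
    for k in range(n_internal):
        max_parent_depth = min(7, max(by_depth))
        d = int(rng.integers(0, max_parent_depth + 1))
        parent = by_depth[d][int(rng.integers(0, len(by_depth[d])))]
        node = f"c{k}"
        g.add_edge(node, parent)
        by_depth.setdefault(d + 1, []).append(node)

    senses: dict[str, set[str]] = {}
    for i, form in enumerate(forms):
        d = depths[i]
        pd_ = d - 1
        while pd_ not in by_depth:
            pd_ -= 1
        parent = by_depth[pd_][int(rng.integers(0, len(by_depth[pd_])))]
        leaf = f"w_{form}"
        g.add_edge(leaf, parent)
        senses[form] = {leaf}
        if rng.random() < spec.polysemy_rate:
            pd2 = int(rng.integers(1, max(by_depth) + 1))
            while pd2 not in by_depth:
                pd2 -= 1
            parent2 = by_depth[pd2][int(rng.integers(0, len(by_depth[pd2])))]
            leaf2 = f"w2_{form}"
            g.add_edge(leaf2, parent2)
            senses[form].add(leaf2)
    taxonomy = TaxonomyGraph(graph=g, senses=senses)
    return lexicon, taxonomy


def make_cohort(
    spec: SyntheticCohortSpec, lexicon: Lexicon, taxonomy: TaxonomyGraph
) -> tuple[list[FluencyResponse], pd.DataFrame]:
    """Generate fluency transcripts and participant metadata.

    Each participant draws a latent severity around their group mean.
    Severity reduces per-task valid counts (by ``count_deficit`` count-SD
    units at severity 1) and biases word sampling through a softmax over a
    per-word utility  sum_p effect_p x severity x z_p(word)  restricted to
    each effect's tasks.  IFS and MoCA scores decline linearly with
    severity, with noise set so the pooled severity-IFS correlation matches
    ``ifs_link``.  Invalid responses (repetitions, digit tokens) and
    unintelligible markers are injected at the spec's rates.

    Returns the (unflagged) responses and a metadata table that includes the
    latent ``severity`` column as generator ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    props = property_table(lexicon, taxonomy)
    zprops = (props - props.mean()) / props.std(ddof=0)
    zprops = zprops.fillna(0.0)
    form_list = list(zprops.index)
    zmat = {p: zprops[p].to_numpy() for p in zprops.columns}

    base_mean, base_sd = spec.base_count
    sev_pool_sd = float(np.sqrt(0.25 + spec.severity_sd**2))
    ifs_noise = (
        spec.ifs_slope * sev_pool_sd * np.sqrt(max(1.0 / spec.ifs_link**2 - 1.0, 0.0))
        if spec.ifs_link > 0
        else 3.0
    )

    responses: list[FluencyResponse] = []
    meta_rows = []
    pid_counter = 0
    for group, n_group in spec.n_per_group.items():
        demo = spec.demographics[group]
        effects = spec.effects.get(group, {})
        for _ in range(n_group):
            pid = f"S{pid_counter:03d}"
            pid_counter += 1
            severity = float(rng.normal(spec.severity_mean[group], spec.severity_sd))
            age = float(np.clip(rng.normal(*demo["age"]), 40, 95))
            education = float(np.clip(rng.normal(*demo["education"]), 0, 25))
            sex = "F" if rng.random() < demo["female"] else "M"
            ifs = float(np.clip(spec.ifs_base - spec.ifs_slope * severity + rng.normal(0, ifs_noise), 0, 30))
            moca = float(np.clip(np.rint(spec.moca_base - spec.moca_slope * severity + rng.normal(0, 2.5)), 0, 30))
            meta_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "sex": sex,
                    "age": round(age, 1),
                    "education": round(education, 1),
                    "handedness": "R" if rng.random() < 0.9 else "L",
                    "moca": moca,
                    "ifs": round(ifs, 1),
                    "severity": round(severity, 4),
                }
            )
            sev_pos = max(severity, 0.0)
            for task in TASKS:
                n_valid = int(
                    max(
                        3,
                        np.rint(
                            rng.normal(
                                base_mean - spec.count_deficit[group] * base_sd * severity,
                                base_sd,
                            )
                        ),
                    )
                )
                utility = np.zeros(len(form_list))
                for prop, (shift, prop_tasks) in effects.items():
                    if task in prop_tasks:
                        utility = utility + spec.utility_gain * shift * sev_pos * zmat[prop]
                w = np.exp(utility - utility.max())
                w /= w.sum()
                k = min(n_valid, len(form_list))
                picks = rng.choice(len(form_list), size=k, replace=False, p=w)
                words = [form_list[i] for i in picks]
                # inject invalid utterances between the valid ones
                uttered: list[str] = []
                for wd in words:
                    if uttered and rng.random() < spec.invalid_repetition_rate:
                        uttered.append(uttered[int(rng.integers(0, len(uttered)))])
                    if rng.random() < spec.invalid_digit_rate:
                        uttered.append(f"{wd}{int(rng.integers(0, 10))}")
                    if rng.random() < spec.unintelligible_rate:
                        uttered.append("xxx")
                    uttered.append(wd)
                for pos, wd in enumerate(uttered, start=1):
                    responses.append(
                        FluencyResponse(
                            participant_id=pid,
                            task=task,
                            position=pos,
                            raw=wd,
                            normalized=wd,
                        )
                    )
    meta = pd.DataFrame(meta_rows).set_index("participant_id", drop=False)
    meta.index.name = None
    return responses, meta


@dataclass
class SyntheticEEGSpec:
    """Parameters of generated multichannel oscillatory EEG.

    Channels mix independent noise with shared band-limited sources; pairs
    of channels coupled to the same source phase-lock in proportion to the
    mixing coefficient.  ``cluster_channels`` index the planted cluster,
    whose coupling is multiplied by ``1 - cluster_reduction`` for the
    ``affected_group``.
    """

    seed: int
    n_channels: int = 32
    n_per_group: dict = field(default_factory=lambda: {"AD": 16, "HC": 14})
    sampling_rate: float = 256.0
    duration_s: float = 20.0
    band: tuple = BETA_BAND
    base_coupling: float = 0.2
    cluster_channels: tuple = tuple(range(10))
    cluster_coupling: float = 0.75
    cluster_reduction: float = 0.5
    affected_group: str = "AD"
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if max(self.cluster_channels, default=-1) >= self.n_channels:
            raise ValueError("cluster channels outside the channel range")
        for c in (self.base_coupling, self.cluster_coupling):
            if not 0.0 <= c <= 1.0:
                raise ValueError("coupling coefficients must lie in [0, 1]")
        if self.duration_s < 2.0:
            raise ValueError("duration must cover at least two 1000-ms segments")


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, band) -> np.ndarray:
    from scipy import signal as sps

    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / y.std()


def make_eeg(spec: SyntheticEEGSpec) -> dict[str, list[SegmentedEEG]]:
    """Generate band-passed, segmented EEG per group.

    Each subject's channels are  sqrt(1 - b^2) * noise + b * source  with
    ``b`` the coupling: all channels share a weak global source at
    ``base_coupling``; cluster channels additionally share a cluster source
    at ``cluster_coupling`` (reduced for the affected group).  PLV between
    generated channels increases monotonically with the mixing coefficient.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 47]))
    n_samp = int(spec.duration_s * spec.sampling_rate)
    out: dict[str, list[SegmentedEEG]] = {}
    cluster = set(spec.cluster_channels)
    for group, n_subj in spec.n_per_group.items():
        reduction = spec.cluster_reduction if group == spec.affected_group else 0.0
        b_cluster = spec.cluster_coupling * (1.0 - reduction)
        subjects = []
        for s in range(n_subj):
            g_src = _bandlimited_noise(rng, n_samp, spec.sampling_rate, spec.band)
            c_src = _bandlimited_noise(rng, n_samp, spec.sampling_rate, spec.band)
            raw = np.empty((spec.n_channels, n_samp))
            for ch in range(spec.n_channels):
                noise = rng.standard_normal(n_samp) * spec.noise_sd
                b = b_cluster if ch in cluster else 0.0
                a = spec.base_coupling
                resid = max(1.0 - a**2 - b**2, 0.05)
                raw[ch] = np.sqrt(resid) * noise + a * g_src + b * c_src
            subjects.append(
                bandpass_and_segment(
                    raw,
                    spec.sampling_rate,
                    band=spec.band,
                    participant_id=f"{group}{s:02d}",
                )
            )
        out[group] = subjects
    return out


def write_cohort(
    out_dir,
    responses: list[FluencyResponse],
    meta: pd.DataFrame,
    lexicon: Lexicon,
    taxonomy: TaxonomyGraph,
) -> None:
    """Write a generated cohort in the pipeline's file formats."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in responses],
            "task": [r.task for r in responses],
            "position": [r.position for r in responses],
            "word": [r.raw for r in responses],
        }
    ).to_csv(out / "transcripts.tsv", sep="\t", index=False)
    meta.drop(columns=["severity"], errors="ignore").to_csv(
        out / "metadata.tsv", sep="\t", index=False
    )
    meta.to_csv(out / "metadata_with_truth.tsv", sep="\t", index=False)
    lexicon.to_tsv(out / "lexicon.tsv")
    with open(out / "taxonomy_edges.tsv", "w", encoding="utf-8") as fh:
        for child, parent in taxonomy.graph.edges:
            fh.write(f"{child}\t{parent}\n")
    with open(out / "taxonomy_senses.tsv", "w", encoding="utf-8") as fh:
        for form, nodes in sorted(taxonomy.senses.items()):
            for node in sorted(nodes):
                fh.write(f"{form}\t{node}\n")
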