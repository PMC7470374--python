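"""Fixed published constants of the three multigene assays.

Gene panels (with per-gene role tags), the Prosigna subtype centroids and
risk-of-recurrence (ROR) weights, the Oncotype DX metagene model, and the
MammaPrint gene70 template are loaded from plain-text files packaged under
``multisig/data``.  Each file carries a provenance header; values that could
not be sourced from the primary publications are clearly labelled synthetic
stand-ins (``*.synthetic.tsv``) and are suitable only for simulation studies.

Everything in this module is a pure function of the packaged files: loading
a constant twice yields identical objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd
import yaml

ASSAYS = ("prosigna", "oncotype", "mammaprint")
SUBTYPES = ("LumA", "LumB", "Her2", "Basal")


class PanelError(ValueError):
    """Malformed or inconsistent packaged constant data."""


def _read_packaged(name: str) -> str:
    return (resources.files("multisig") / "data" / name).read_text()


def _read_tsv(name: str, **kw) -> pd.DataFrame:
    return pd.read_csv(StringIO(_read_packaged(name)), sep="\t", comment="#", **kw)


@dataclass(frozen=True)
class GenePanel:
    """One assay's gene list: reporter genes with role tags plus the
    designated reference (housekeeping) genes used for normalization."""

    assay_name: str
    reporter_genes: tuple[str, ...]
    housekeeping_genes: tuple[str, ...]
    role_map: dict[str, str] = field(hash=False)

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g in self.reporter_genes if self.role_map[g] == role]

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.reporter_genes + self.housekeeping_genes

    def validate(self) -> None:
        if set(self.reporter_genes) & set(self.housekeeping_genes):
            raise PanelError(f"{self.assay_name}: reporter/housekeeping overlap")
        if len(set(self.reporter_genes)) != len(self.reporter_genes):
            raise PanelError(f"{self.assay_name}: duplicate reporter genes")
        expected = {"prosigna": (46, 8), "oncotype": (16, 5), "mammaprint": (70, 0)}
        n_rep, n_hk = expected[self.assay_name]
        if len(self.reporter_genes) != n_rep or len(self.housekeeping_genes) != n_hk:
            raise PanelError(
                f"{self.assay_name}: expected {n_rep} reporters / {n_hk} "
                f"housekeeping, found {len(self.reporter_genes)} / "
                f"{len(self.housekeeping_genes)}"
            )
        if self.assay_name == "prosigna":
            n_prolif = len(self.genes_with_role("proliferation"))
            if n_prolif != 18:
                raise PanelError(f"prosigna: {n_prolif} proliferation genes, need 18")
        if self.assay_name == "oncotype":
            counts = {
                "proliferation": 5, "her2": 2, "er": 4, "invasion": 2, "singleton": 3,
            }
            for role, n in counts.items():
                found = len(self.genes_with_role(role))
                if found != n:
                    raise PanelError(f"oncotype: role {role} has {found}, need {n}")


@dataclass(frozen=True)
class SubtypeCentroids:
    """Reference row-scaled 46-gene expression profile of each intrinsic
    subtype (LumA, LumB, HER2-enriched, Basal-like)."""

    genes: tuple[str, ...]
    subtypes: tuple[str, ...]
    values: np.ndarray  # genes x subtypes

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes),
                            columns=list(self.subtypes))


@dataclass(frozen=True)
class RorWeights:
    """Coefficients of the ROR linear combination (4 subtype correlations,
    proliferation score, tumour-size indicator) and the affine constants
    mapping the raw combination onto the reported 0-100 scale."""

    subtype_weights: dict[str, float]
    proliferation_weight: float
    size_weight: float
    rescale_offset: float
    rescale_slope: float

    def validate(self) -> None:
        if len(self.subtype_weights) != 4:
            raise PanelError("ROR weights: need exactly 4 subtype coefficients")
        vals = [*self.subtype_weights.values(), self.proliferation_weight,
                self.size_weight, self.rescale_offset, self.rescale_slope]
        if not np.all(np.isfinite(vals)):
            raise PanelError("ROR weights: non-finite coefficient")
        if self.rescale_slope <= 0:
            raise PanelError("ROR weights: rescale slope must be positive")


@dataclass(frozen=True)
class MetageneModel:
    """Oncotype DX Recurrence Score model: metagene membership with per-gene
    averaging weights, metagene coefficients, the 0-100 rescale, and the two
    data-quality rules (GSTM1 thresholded at background, Cathepsin-L2
    excluded from the invasion metagene)."""

    metagene_definitions: dict[str, list[tuple[str, float]]]
    metagene_weights: dict[str, float]
    rs_rescale_offset: float
    rs_rescale_slope: float
    gstm1_threshold_rule: bool = True
    ctsl2_excluded: bool = True

    @property
    def metagenes(self) -> tuple[str, ...]:
        return tuple(self.metagene_weights)

    def validate(self, panel: GenePanel) -> None:
        for mg, members in self.metagene_definitions.items():
            for gene, w in members:
                if gene not in panel.reporter_genes:
                    raise PanelError(f"metagene {mg}: {gene} not in oncotype panel")
                if w <= 0:
                    raise PanelError(f"metagene {mg}: nonpositive weight for {gene}")
        if self.rs_rescale_slope <= 0:
            raise PanelError("RS rescale slope must be positive")
        if set(self.metagene_definitions) != set(self.metagene_weights):
            raise PanelError("metagene definitions and weights disagree")


@dataclass(frozen=True)
class Gene70Template:
    """MammaPrint good-prognosis average profile and the correlation cutoff
    separating low (index >= cutoff) from high risk."""

    genes: tuple[str, ...]
    template_profile: np.ndarray
    correlation_cutoff: float

    def validate(self, panel: GenePanel) -> None:
        if self.genes != panel.reporter_genes:
            raise PanelError("gene70 template gene order != mammaprint panel order")
        if not (-1.0 < self.correlation_cutoff < 1.0):
            raise PanelError("gene70 cutoff must lie in (-1, 1)")
        if not np.all(np.isfinite(self.template_profile)):
            raise PanelError("gene70 template contains non-finite values")


def load_aliases() -> dict[str, str]:
    """Legacy-symbol -> panel-symbol map, upper-cased keys."""
    df = _read_tsv("gene_aliases.tsv")
    return {a.strip().upper(): s.strip() for a, s in zip(df["alias"], df["symbol"])}


def resolve_symbol(symbol: str, panel: GenePanel,
                   aliases: dict[str, str] | None = None) -> str | None:
    """Resolve ``symbol`` to a panel gene, case-insensitively and through the
    packaged alias table; returns None when the symbol is not on the panel."""
    if aliases is None:
        aliases = load_aliases()
    s = symbol.strip().upper()
    s = aliases.get(s, s)
    if isinstance(s, str):
        s = s.upper()
    for g in panel.all_genes:
        if g.upper() == s:
            return g
    return None


def load_panel(assay_name: str) -> GenePanel:
    """Load one assay's gene panel from the packaged panel definition."""
    if assay_name not in ASSAYS:
        raise PanelError(f"unknown assay {assay_name!r}; expected one of {ASSAYS}")
    entry = yaml.safe_load(_read_packaged("panels.yaml"))[assay_name]
    reporters = tuple(entry["reporters"])
    role_map = dict(entry["reporters"])
    for hk in entry["housekeeping"]:
        role_map[hk] = "housekeeping"
    panel = GenePanel(
        assay_name=assay_name,
        reporter_genes=reporters,
        housekeeping_genes=tuple(entry["housekeeping"]),
        role_map=role_map,
    )
    panel.validate()
    return panel


def _named_values(name: str) -> dict[str, float]:
    df = _read_tsv(name)
    return dict(zip(df["name"], df["value"].astype(float)))


def load_centroids() -> SubtypeCentroids:
    panel = load_panel("prosigna")
    df = _read_tsv("prosigna_centroids.synthetic.tsv", index_col=0)
    if tuple(df.index) != panel.reporter_genes:
        raise PanelError("centroid gene order != prosigna panel reporter order")
    if tuple(df.columns) != SUBTYPES:
        raise PanelError(f"centroid subtypes must be {SUBTYPES}")
    values = df.to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise PanelError("centroid matrix contains missing values")
    return SubtypeCentroids(genes=panel.reporter_genes, subtypes=SUBTYPES,
                            values=values)


def load_ror_weights() -> RorWeights:
    vals = _named_values("prosigna_ror_weights.synthetic.tsv")
    w = RorWeights(
        subtype_weights={s: vals[f"subtype_{s}"] for s in SUBTYPES},
        proliferation_weight=vals["proliferation"],
        size_weight=vals["size"],
        rescale_offset=vals["rescale_offset"],
        rescale_slope=vals["rescale_slope"],
    )
    w.validate()
    return w


def load_metagene_model(gstm1_threshold_rule: bool = True,
                        ctsl2_excluded: bool = True) -> MetageneModel:
    members = _read_tsv("oncotype_metagenes.tsv")
    defs: dict[str, list[tuple[str, float]]] = {}
    for gene, mg, w in zip(members["gene"], members["metagene"], members["weight"]):
        defs.setdefault(mg, []).append((gene, float(w)))
    vals = _named_values("oncotype_weights.tsv")
    offset = vals.pop("rs_rescale_offset")
    slope = vals.pop("rs_rescale_slope")
    model = MetageneModel(
        metagene_definitions=defs,
        metagene_weights={k: float(v) for k, v in vals.items()},
        rs_rescale_offset=offset,
        rs_rescale_slope=slope,
        gstm1_threshold_rule=gstm1_threshold_rule,
        ctsl2_excluded=ctsl2_excluded,
    )
    model.validate(load_panel("oncotype"))
    return model


def load_gene70_template() -> Gene70Template:
    panel = load_panel("mammaprint")
    text = _read_packaged("gene70_template.synthetic.tsv")
    cutoff = None
    for line in text.splitlines():
        if line.startswith("# correlation_cutoff"):
            cutoff = float(line.split("\t")[1])
    if cutoff is None:
        raise PanelError("gene70 template file lacks a correlation_cutoff header")
    df = pd.read_csv(StringIO(text), sep="\t", comment="#", index_col=0)
    tpl = Gene70Template(
        genes=tuple(df.index),
        template_profile=df["template"].to_numpy(float),
        correlation_cutoff=cutoff,
    )
    tpl.validate(panel)
    return tpl


def load_constants(assay_name: str):
    """Load the scoring constants of one assay.

    Returns ``(SubtypeCentroids, RorWeights)`` for prosigna, a
    ``MetageneModel`` for oncotype and a ``Gene70Template`` for mammaprint.
    """
    if assay_name == "prosigna":
        return load_centroids(), load_ror_weights()
    if assay_name == "oncotype":
        return load_metagene_model()
    if assay_name == "mammaprint":
        return load_gene70_template()
    raise PanelError(f"unknown assay {assay_name!r}; expected one of {ASSAYS}")
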