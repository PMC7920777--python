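"""Binary cells × taxa incidence table — the central object all metrics consume.

A :class:`PresenceMatrix` records which taxa occur in which grid cells.
Column sums are taxon range sizes (the number of cells a taxon occupies,
the denominator of weighted endemism); row sums are per-cell taxon
richness. Entries are strictly 0/1: multiple records of a taxon in one
cell collapse to a single presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PresenceMatrix"]


@dataclass
class PresenceMatrix:
    """Presence–absence incidence of taxa across grid cells.

    Parameters
    ----------
    cells : list of str
        Ordered cell identifiers ("r<row>_c<col>").
    taxa : list of str
        Ordered taxon names.
    incidence : ndarray of shape (n_cells, n_taxa)
        Binary matrix; entry (c, t) is 1 iff taxon t occurs in cell c.
    """

    cells: list[str]
    taxa: list[str]
    incidence: np.ndarray
    empty_cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=np.uint8)
        if self.incidence.shape != (len(self.cells), len(self.taxa)):
            raise ValueError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.cells)} cells x {len(self.taxa)} taxa"
            )
        if not np.isin(self.incidence, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")

    # -- derived quantities -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def ranges(self) -> np.ndarray:
        """Per-taxon range size r_t = number of occupied cells (column sums)."""
        return self.incidence.sum(axis=0).astype(np.int64)

    @property
    def richness(self) -> np.ndarray:
        """Per-cell taxon richness k_c (row sums)."""
        return self.incidence.sum(axis=1).astype(np.int64)

    def cell_index(self, cell_id: str) -> int:
        return self.cells.index(cell_id)

    def taxa_in_cell(self, cell_id: str) -> set[str]:
        row = self.incidence[self.cell_index(cell_id)]
        return {t for t, v in zip(self.taxa, row) if v}

    def cells_of_taxon(self, taxon: str) -> set[str]:
        col = self.incidence[:, self.taxa.index(taxon)]
        return {c for c, v in zip(self.cells, col) if v}

    # -- construction / filtering -------------------------------------------

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, str]], cells: list[str] | None = None,
        taxa: list[str] | None = None,
    ) -> "PresenceMatrix":
        """Build from (cell_id, taxon) presence pairs.

        Orders default to first-appearance order of the pairs.
        """
        if cells is None:
            cells = list(dict.fromkeys(c for c, _ in pairs))
        if taxa is None:
            taxa = list(dict.fromkeys(t for _, t in pairs))
        ci = {c: i for i, c in enumerate(cells)}
        ti = {t: i for i, t in enumerate(taxa)}
        X = np.zeros((len(cells), len(taxa)), dtype=np.uint8)
        for c, t in pairs:
            X[ci[c], ti[t]] = 1
        return cls(cells=cells, taxa=taxa, incidence=X)

    def drop_empty(self) -> "PresenceMatrix":
        """Drop all-zero taxa and record/remove empty cells.

        Empty cells are the study region's "no records" cells; they are
        excluded from every downstream metric and kept on ``empty_cells``
        so outputs can still emit them as nulls.
        """
        keep_t = self.incidence.sum(axis=0) > 0
        keep_c = self.incidence.sum(axis=1) > 0
        empty = [c for c, k in zip(self.cells, keep_c) if not k]
        return PresenceMatrix(
            cells=[c for c, k in zip(self.cells, keep_c) if k],
            taxa=[t for t, k in zip(self.taxa, keep_t) if k],
            incidence=self.incidence[np.ix_(keep_c, keep_t)],
            empty_cells=self.empty_cells + empty,
        )

    def select_taxa(self, taxa: list[str]) -> "PresenceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return PresenceMatrix(
            cells=list(self.cells), taxa=list(taxa),
            incidence=self.incidence[:, idx], empty_cells=list(self.empty_cells),
        )

    def with_incidence(self, X: np.ndarray) -> "PresenceMatrix":
        """Same cells/taxa, different incidence (used by the null model)."""
        return PresenceMatrix(
            cells=list(self.cells), taxa=list(self.taxa), incidence=X,
            empty_cells=list(self.empty_cells),
        )

    # -- IO ------------------------------------------------------------------

    def to_pairs_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.incidence)
        return pd.DataFrame(
            {"cell_id": [self.cells[r] for r in rows],
             "taxon": [self.taxa[c] for c in cols]}
        )

    def write_pairs_csv(self, path) -> None:
        """Sparse (cell_id, taxon) CSV serialization."""
        self.to_pairs_frame().to_csv(path, index=False)

    @classmethod
    def read_pairs_csv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path)
        return cls.from_pairs(list(zip(df["cell_id"], df["taxon"])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=self.cells, columns=self.taxa)
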