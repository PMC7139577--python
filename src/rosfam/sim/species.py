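"""Species tree for the four-taxon ingroup plus a distant outgroup.

The default study system is four closely related *Eucalyptus* species —
*E. camaldulensis* splitting first, then *E. gunnii*, and finally
*E. grandis* / *E. globulus* — with *Arabidopsis thaliana* as a distant
outgroup whose divergence provides the single time calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_ORGANISMS = ("camaldulensis", "gunnii", "grandis", "globulus")
DEFAULT_OUTGROUP = "outgroup"
#: split ages in MYA: grandis/globulus, gunnii, camaldulensis, outgroup
DEFAULT_SPLIT_AGES = (0.15, 0.89, 1.27, 112.0)


@dataclass
class TreeNode:
    """Node of a rooted, ultrametric species tree. Ages in MYA; leaves at 0."""

    label: str
    age: float
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float:
        """Length in MY of the branch above this node."""
        return 0.0 if self.parent is None else self.parent.age - self.age

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class SpeciesTree:
    root: TreeNode
    calibration_node: TreeNode
    calibration_age: float

    def __post_init__(self) -> None:
        if abs(self.calibration_node.age - self.calibration_age) > 1e-12:
            raise ValueError("calibration node age differs from calibration age")
        for leaf in self.root.leaves():
            if leaf.age != 0.0:
                raise ValueError(f"leaf {leaf.label} not at age 0 (not ultrametric)")
        for node in self.preorder():
            for c in node.children:
                if not c.age < node.age:
                    raise ValueError(
                        f"child {c.label} age {c.age} not below parent {node.age}"
                    )

    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.label
            if node.parent is None:
                return core
            return f"{core}:{node.branch_length:g}"

        return fmt(self.root) + ";"


def simulate_species_history(
    ages=DEFAULT_SPLIT_AGES,
    organisms=DEFAULT_ORGANISMS,
    outgroup: str = DEFAULT_OUTGROUP,
) -> SpeciesTree:
    """Build the default-topology species tree from four split ages.

    ``ages`` are, youngest first: the grandis/globulus-type split, the gunnii
    split, the camaldulensis split, and the outgroup (calibration) split.
    The topology is ((cam,(gun,(gra,glo))),outgroup).  Deterministic.
    """
    if len(ages) != 4 or len(organisms) != 4:
        raise ValueError("need exactly four split ages and four ingroup organisms")
    a1, a2, a3, a4 = (float(a) for a in ages)
    if not (0.0 < a1 < a2 < a3 < a4):
        raise ValueError(
            f"split ages must be strictly increasing and positive, got {ages}"
        )
    cam, gun, gra, glo = organisms
    n_gg = TreeNode(label="anc_" + gra + "_" + glo, age=a1)
    n_gg.children = [TreeNode(gra, 0.0, parent=n_gg), TreeNode(glo, 0.0, parent=n_gg)]
    n_gun = TreeNode(label="anc_" + gun, age=a2)
    n_gun.children = [TreeNode(gun, 0.0, parent=n_gun), n_gg]
    n_gg.parent = n_gun
    n_cam = TreeNode(label="anc_ingroup", age=a3)
    n_cam.children = [TreeNode(cam, 0.0, parent=n_cam), n_gun]
    n_gun.parent = n_cam
    root = TreeNode(label="root", age=a4)
    root.children = [n_cam, TreeNode(outgroup, 0.0, parent=root)]
    n_cam.parent = root
    return SpeciesTree(root=root, calibration_node=root, calibration_age=a4)


def ingroup_tree(ages=DEFAULT_SPLIT_AGES[:3], organisms=DEFAULT_ORGANISMS) -> SpeciesTree:
    """Species tree restricted to the four-taxon ingroup (no outgroup).

    Useful for family-evolution simulations where the deep outgroup branch
    would only add saturation; the root is the camaldulensis split.
    """
    a1, a2, a3 = (float(a) for a in ages)
    if not (0.0 < a1 < a2 < a3):
        raise ValueError(f"split ages must be strictly increasing, got {ages}")
    cam, gun, gra, glo = organisms
    n_gg = TreeNode(label="anc_" + gra + "_" + glo, age=a1)
    n_gg.children = [TreeNode(gra, 0.0, parent=n_gg), TreeNode(glo, 0.0, parent=n_gg)]
    n_gun = TreeNode(label="anc_" + gun, age=a2)
    n_gun.children = [TreeNode(gun, 0.0, parent=n_gun), n_gg]
    n_gg.parent = n_gun
    root = TreeNode(label="root", age=a3)
    root.children = [TreeNode(cam, 0.0, parent=root), n_gun]
    n_gun.parent = root
    return SpeciesTree(root=root, calibration_node=root, calibration_age=a3)
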