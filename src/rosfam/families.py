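"""The 11 gene families of the reactive-oxygen-species (ROS) gene network.

The network comprises ten peroxidase families — ascorbate peroxidase (APx),
ascorbate peroxidase-related (APx-R), catalase (Kat), glutathione peroxidase
(GPx), alpha-dioxygenase (DiOx), class III peroxidase (CIII Prx) and the four
peroxiredoxins (1CysPrx, 2CysPrx, PrxII, PrxQ) — plus the respiratory burst
oxidase homologues (Rboh, NADPH oxidases).
"""

ROS_FAMILIES = (
    "1CysPrx",
    "2CysPrx",
    "APx",
    "APx-R",
    "CIII Prx",
    "DiOx",
    "GPx",
    "Kat",
    "PrxII",
    "PrxQ",
    "Rboh",
)

#: short family tags used inside gene names (e.g. EgrPrx01 for a CIII Prx).
FAMILY_ABBREV = {
    "1CysPrx": "1CysPrx",
    "2CysPrx": "2CysPrx",
    "APx": "APx",
    "APx-R": "APx-R",
    "CIII Prx": "Prx",
    "DiOx": "DiOx",
    "GPx": "GPx",
    "Kat": "Kat",
    "PrxII": "PrxII",
    "PrxQ": "PrxQ",
    "Rboh": "Rboh",
}


def check_family(name: str) -> str:
    """Validate a family label, returning it unchanged."""
    if name not in ROS_FAMILIES:
        raise ValueError(f"unknown ROS family label: {name!r}")
    return name
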