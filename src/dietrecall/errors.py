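"""Exception hierarchy for the dietrecall package."""


class DietRecallError(Exception):
    """Base class for all package-specific errors."""


class FCTError(DietRecallError):
    """Malformed food-composition table or recipe registry."""


class IngestError(DietRecallError):
    """Structurally invalid recall export (orphans, duplicates, bad schema)."""


class PortionError(DietRecallError):
    """Malformed portion-size database."""


class PortionLookupError(DietRecallError):
    """No food-specific or group-level portion entry matched a meal record."""

    def __init__(self, food_code: str, food_group: str | None, utensil: str, size: str):
        self.food_code = food_code
        self.food_group = food_group
        self.utensil = utensil
        self.size = size
        super().__init__(
            f"no portion entry for food {food_code!r} "
            f"(group {food_group!r}) with utensil {utensil!r} size {size!r}"
        )
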