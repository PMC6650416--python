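"""Exception hierarchy for the GT standard toolkit."""


class GtsError(Exception):
    """Base class for all toolkit errors."""


class MalformedSequenceError(GtsError):
    """Input contained characters outside the A/C/G/T alphabet."""


class RegistryError(GtsError):
    """Bad part registry content (duplicate or unknown ids, bad types)."""


class DesignError(GtsError):
    """An oligo or barcode design step could not satisfy its constraints."""


class PrimerDesignError(DesignError):
    """No primer binding length in range reaches the Tm threshold."""


class SeDesignError(DesignError):
    """No sticky-end length in range passes Tm and self-ligation screens."""

    def __init__(self, message: str, diagnosis: dict | None = None) -> None:
        super().__init__(message)
        self.diagnosis = diagnosis or {}


class InternalSiteError(DesignError):
    """Fragment carries an internal recognition site of the chosen enzyme."""


class NoRouteError(DesignError):
    """No fragment-preparation route satisfies the requested options."""

    def __init__(self, message: str, blocking_sites: dict | None = None) -> None:
        super().__init__(message)
        self.blocking_sites = blocking_sites or {}


class NoSynonymousFixError(DesignError):
    """A recognition site cannot be removed without changing the protein."""


class UnknownEnzymeError(GtsError):
    """Enzyme name not present in the bundled definition table."""


class DesignValidationError(GtsError):
    """An assembly design violates the standard's grammar rules."""


class SimulationError(GtsError):
    """Strand-level simulation failed or contradicted the declared design."""


class OverhangMismatchError(SimulationError):
    """Sticky ends offered to each other are not complementary."""


class NotAHairpinError(SimulationError):
    """An oligo submitted as a Boligo does not fold into the required hairpin."""


class AmbiguousAssemblyError(SimulationError):
    """A junction has more than one complementary partner."""

    def __init__(self, message: str, conflicts: list | None = None) -> None:
        super().__init__(message)
        self.conflicts = conflicts or []


class NoCircularProductError(SimulationError):
    """No closed circular product can be formed from the given pieces."""


class PrimerNotFoundError(SimulationError):
    """A colony-PCR primer has no exact match on the product."""
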