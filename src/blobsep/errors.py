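"""Exception hierarchy shared across blobsep modules."""


class BlobsepError(Exception):
    """Base class for all blobsep errors."""


class MalformedRecordError(BlobsepError):
    """A sequence record violates its own invariants (e.g. seq/qual length mismatch)."""


class PairingError(BlobsepError):
    """Paired read files are desynchronized (mate IDs do not match)."""


class FormatError(BlobsepError):
    """An input file violates its format contract (empty FASTA, duplicate IDs, ...)."""


class ConsistencyError(BlobsepError):
    """Cross-file references do not resolve (alignment/hit names an unknown contig)."""


class EstimationError(BlobsepError):
    """A statistical estimate cannot be formed (e.g. no proper pairs for insert size)."""


class IntegrityError(BlobsepError):
    """An output would be incomplete (a selected read pair is missing from the input)."""


class UnknownTaxidError(BlobsepError, LookupError):
    """A taxid is absent from the taxonomy table (distinct from rank-unresolved)."""
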