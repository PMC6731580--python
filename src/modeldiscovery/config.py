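"""Shared configuration: paths, ranking weights and remote endpoints.

All remote services (SPARQL query endpoint, label lookup, dbfetch, multiple
alignment) default to *disabled*; nothing in the package touches the network
unless a config explicitly turns a service on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .search import DEFAULT_WEIGHTS, validate_weights


@dataclass
class RemoteService:
    enabled: bool = False
    url: str = ""
    timeout: float = 30.0
    retries: int = 2


@dataclass
class Config:
    corpus_dir: Optional[str] = None
    dictionary_path: Optional[str] = None
    prefix_registry_path: Optional[str] = None
    labels_path: Optional[str] = None
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    query_endpoint: RemoteService = field(default_factory=RemoteService)
    label_lookup: RemoteService = field(
        default_factory=lambda: RemoteService(url="https://www.ebi.ac.uk/ols4/api")
    )
    dbfetch: RemoteService = field(
        default_factory=lambda: RemoteService(
            url="https://www.ebi.ac.uk/Tools/dbfetch/dbfetch"
        )
    )
    msa: RemoteService = field(
        default_factory=lambda: RemoteService(
            url="https://www.ebi.ac.uk/Tools/services/rest/clustalo"
        )
    )
    log_level: str = "WARNING"

    def __post_init__(self):
        validate_weights(self.weights)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("corpus_dir", "dictionary_path", "prefix_registry_path",
                    "labels_path", "log_level"):
            if key in data:
                kwargs[key] = data[key]
        if "weights" in data:
            kwargs["weights"] = dict(data["weights"])
        for key in ("query_endpoint", "label_lookup", "dbfetch", "msa"):
            if key in data:
                kwargs[key] = RemoteService(**data[key])
        return cls(**kwargs)
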