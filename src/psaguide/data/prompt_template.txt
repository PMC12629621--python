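{persona}

### SOURCE: {source}

### CASE
{case_json}

### GUIDELINE CONTEXT
{context}

### INSTRUCTIONS
{reasoning}

### OUTPUT FORMAT
Respond with a single JSON object exactly in this shape:
{output_schema}
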