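<?xml version="1.0" encoding="UTF-8"?>
<!-- Example EML 2.2 document (authored for this package) with attribute-level
     unit declarations in several ad hoc styles. -->
<eml:eml xmlns:eml="https://eml.ecoinformatics.org/eml-2.2.0"
         packageId="knb-lter-exa.101.4" system="https://pasta.edirepository.org">
  <dataset>
    <title>Soil pore water chemistry and litterfall at an example site</title>
    <creator>
      <individualName>
        <givenName>Ada</givenName>
        <surName>Example</surName>
      </individualName>
      <organizationName>Example LTER</organizationName>
    </creator>
    <dataTable>
      <entityName>porewater_chemistry</entityName>
      <entityDescription>Phosphate concentration in soil pore water</entityDescription>
      <attributeList>
        <attribute id="po4">
          <attributeName>phosphate</attributeName>
          <attributeDefinition>Phosphate concentration in interstitial water</attributeDefinition>
          <measurementScale>
            <ratio>
              <unit>
                <customUnit>micromolesPerLiter</customUnit>
              </unit>
              <numericDomain>
                <numberType>real</numberType>
              </numericDomain>
            </ratio>
          </measurementScale>
        </attribute>
        <attribute>
          <attributeName>litterfall</attributeName>
          <attributeDefinition>Litterfall dry mass per ground area</attributeDefinition>
          <measurementScale>
            <ratio>
              <unit>
                <customUnit>g/m^2</customUnit>
              </unit>
            </ratio>
          </measurementScale>
        </attribute>
        <attribute>
          <attributeName>soil_temp</attributeName>
          <attributeDefinition>Soil temperature at 10 cm depth</attributeDefinition>
          <measurementScale>
            <interval>
              <unit>
                <standardUnit>celsius</standardUnit>
              </unit>
            </interval>
          </measurementScale>
        </attribute>
        <attribute>
          <attributeName>site_code</attributeName>
          <attributeDefinition>Site identifier</attributeDefinition>
          <measurementScale>
            <nominal>
              <nonNumericDomain>
                <textDomain>
                  <definition>site code</definition>
                </textDomain>
              </nonNumericDomain>
            </nominal>
          </measurementScale>
        </attribute>
        <attribute>
          <attributeName>field_note</attributeName>
          <attributeDefinition>Free-text note with a misplaced unit entry</attributeDefinition>
          <measurementScale>
            <ratio>
              <unit>
                <customUnit>atlantis/alvin</customUnit>
              </unit>
            </ratio>
          </measurementScale>
        </attribute>
      </attributeList>
    </dataTable>
  </dataset>
</eml:eml>
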